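"""Synthetic multi-omic cell-line panels with known ground truth.

Emulates a small cancer cell-line panel profiled in three layers — whole
proteome (WP), global phosphoproteome (PP), and phosphotyrosine sites (YP) —
with planted structure at every level the downstream pipeline is supposed to
recover:

* subtype structure: lines are assigned round-robin to ``k_true`` subtypes;
  WP and YP express the full ``k_true``-way split, while PP expresses the
  2-way super-grouping obtained by merging the first ``ceil(k_true/2)``
  subtypes (so integrative clustering has a planted hierarchy to find);
* a kinase-substrate network: each synthetic kinase is itself a protein in
  WP carrying two of its own phosphosites in PP and YP, plus disjoint
  substrate site sets in PP and YP;
* differential kinase activity: the substrate (and own) sites of planted
  active kinases are shifted by ``planted_activity_delta`` in the favored
  super-group;
* per-line outlier kinases: a few (kinase, line) pairs get a large intensity
  bump on the kinase's WP row and its own PP/YP sites.

Intensities are simulated directly on the log2 scale as Gaussian blocks
(baseline N(20, 2) per feature); replicates of a line share the line's mean
vector exactly and differ by noise with SD ``noise_sd / 2``. Missingness is
Bernoulli with a logistic intensity dependence (left-censoring-like when
``dropout_bias > 0``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .kinact import KinaseSubstrateMap
from .matrix import OmicsMatrix, write_matrix


@dataclass
class SynthConfig:
    """Panel-generation parameters; identical seeds give identical panels."""

    n_lines: int = 14
    n_replicates: int = 2
    k_true: int = 3
    n_proteins: int = 600
    n_sites: int = 800
    n_ysites: int = 300
    separation: float = 4.0
    frac_subtype_features: float = 0.25
    noise_sd: float = 0.5
    dropout_rate: float = 0.0
    dropout_bias: float = 1.0
    n_kinases: int = 20
    substrates_per_kinase: int = 10
    planted_activity_delta: float = 3.0
    n_active_kinases: int | None = None
    n_outliers: int = 2
    outlier_magnitude: float = 8.0
    batch_shift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_lines", "n_replicates", "k_true", "n_proteins", "n_sites",
                     "n_ysites", "n_kinases", "substrates_per_kinase"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("frac_subtype_features", "dropout_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.dropout_rate >= 1:
            raise ValueError("dropout_rate must be < 1")
        if self.k_true > self.n_lines:
            raise ValueError("k_true cannot exceed n_lines")
        needed = self.n_kinases * self.substrates_per_kinase
        if needed > self.n_sites:
            raise ValueError(
                f"n_kinases * substrates_per_kinase = {needed} exceeds n_sites = {self.n_sites}"
            )
        if needed > self.n_ysites:
            raise ValueError(
                f"n_kinases * substrates_per_kinase = {needed} exceeds n_ysites = {self.n_ysites}"
            )

    @property
    def n_active(self) -> int:
        if self.n_active_kinases is not None:
            return self.n_active_kinases
        return max(1, self.n_kinases // 4)


@dataclass
class SynthPanel:
    """A generated panel plus every piece of planted ground truth."""

    wp: OmicsMatrix
    pp: OmicsMatrix
    yp: OmicsMatrix
    truth_labels: pd.Series          # line -> subtype (0..k_true-1)
    truth_super: pd.Series           # line -> super-group (0/1)
    sample_to_line: pd.Series        # sample id -> line id
    ks_map: KinaseSubstrateMap
    site_to_protein: dict[str, str]
    planted_outliers: list[tuple[str, str]] = field(default_factory=list)
    planted_active_kinases: dict[str, int] = field(default_factory=dict)
    config: SynthConfig | None = None

    @property
    def layers(self) -> dict[str, OmicsMatrix]:
        return {"WP": self.wp, "PP": self.pp, "YP": self.yp}

    def sample_truth(self, level: str = "subtype") -> pd.Series:
        """Per-sample planted labels (``subtype`` or ``super``)."""
        src = self.truth_labels if level == "subtype" else self.truth_super
        return self.sample_to_line.map(src)

    def super_group_samples(self) -> tuple[list[str], list[str]]:
        """Sample ids of super-group 0 and 1."""
        t = self.sample_truth("super")
        return (sorted(t.index[t == 0]), sorted(t.index[t == 1]))


def _simulate_layer(
    rng: np.random.Generator,
    features: list[str],
    signal_pool: list[str],
    line_groups: pd.Series,
    n_groups: int,
    cfg: SynthConfig,
    samples: list[str],
    sample_to_line: pd.Series,
) -> tuple[pd.DataFrame, dict[str, int]]:
    n_feat = len(features)
    idx = {f: i for i, f in enumerate(features)}
    baseline = rng.normal(20.0, 2.0, size=n_feat)
    n_signal = int(round(cfg.frac_subtype_features * n_feat))
    chosen = list(rng.choice(len(signal_pool), size=min(n_signal, len(signal_pool)),
                             replace=False))
    assign = {signal_pool[i]: g % n_groups for g, i in enumerate(chosen)}

    lines = list(line_groups.index)
    line_mean = np.empty((n_feat, len(lines)))
    for j, line in enumerate(lines):
        shift = np.zeros(n_feat)
        for f, g in assign.items():
            if line_groups[line] == g:
                shift[idx[f]] = cfg.separation
        line_mean[:, j] = baseline + shift + rng.normal(0.0, cfg.noise_sd, size=n_feat)

    col_of_line = {line: j for j, line in enumerate(lines)}
    X = np.empty((n_feat, len(samples)))
    for s_j, s in enumerate(samples):
        j = col_of_line[sample_to_line[s]]
        X[:, s_j] = line_mean[:, j] + rng.normal(0.0, cfg.noise_sd / 2.0, size=n_feat)
    return pd.DataFrame(X, index=features, columns=samples), assign


def generate_panel(config: SynthConfig) -> SynthPanel:
    """Generate a full three-layer panel from a :class:`SynthConfig`."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    lines = [f"L{i + 1:02d}" for i in range(cfg.n_lines)]
    truth = pd.Series({line: i % cfg.k_true for i, line in enumerate(lines)})
    first_half = math.ceil(cfg.k_true / 2)
    truth_super = pd.Series({line: 0 if truth[line] < first_half else 1 for line in lines})
    samples = [f"{line}_R{r + 1}" for line in lines for r in range(cfg.n_replicates)]
    sample_to_line = pd.Series({s: s.rsplit("_R", 1)[0] for s in samples})

    kinases = [f"KIN{j + 1:02d}" for j in range(cfg.n_kinases)]
    proteins = [f"P{i + 1:04d}" for i in range(cfg.n_proteins)] + kinases

    # PP sites: generic sites on random host proteins + each kinase's own 2 sites
    host = rng.choice(cfg.n_proteins, size=cfg.n_sites)
    pp_sites = []
    site_to_protein: dict[str, str] = {}
    positions_used: dict[str, set[int]] = {}
    for i in range(cfg.n_sites):
        prot = proteins[int(host[i])]
        pos = _fresh_position(rng, positions_used.setdefault(prot, set()))
        res = "S" if rng.random() < 0.7 else "T"
        key = f"{prot}_{res}{pos}"
        pp_sites.append(key)
        site_to_protein[key] = prot
    own_pp: dict[str, set[str]] = {}
    own_yp: dict[str, set[str]] = {}
    for kin in kinases:
        own_pp[kin] = set()
        own_yp[kin] = set()
        used = positions_used.setdefault(kin, set())
        for _ in range(2):
            key = f"{kin}_S{_fresh_position(rng, used)}"
            own_pp[kin].add(key)
            site_to_protein[key] = kin
        for _ in range(2):
            key = f"{kin}_Y{_fresh_position(rng, used)}"
            own_yp[kin].add(key)
            site_to_protein[key] = kin
    pp_features = pp_sites + sorted(set().union(*own_pp.values()))

    # YP sites: generic tyrosine sites + kinase own Y sites
    host_y = rng.choice(cfg.n_proteins, size=cfg.n_ysites)
    yp_sites = []
    for i in range(cfg.n_ysites):
        prot = proteins[int(host_y[i])]
        key = f"{prot}_Y{_fresh_position(rng, positions_used.setdefault(prot, set()))}"
        yp_sites.append(key)
        site_to_protein[key] = prot
    yp_features = yp_sites + sorted(set().union(*own_yp.values()))

    # disjoint substrate sets per kinase in PP and in YP
    pp_perm = rng.permutation(cfg.n_sites)
    yp_perm = rng.permutation(cfg.n_ysites)
    substrates: dict[str, set[str]] = {}
    yp_substrates: dict[str, set[str]] = {}
    s = cfg.substrates_per_kinase
    for j, kin in enumerate(kinases):
        substrates[kin] = {pp_sites[i] for i in pp_perm[j * s:(j + 1) * s]}
        yp_substrates[kin] = {yp_sites[i] for i in yp_perm[j * s:(j + 1) * s]}
    ks_map = KinaseSubstrateMap(
        substrates={k: substrates[k] | yp_substrates[k] for k in kinases},
        own_sites={k: own_pp[k] | own_yp[k] for k in kinases},
    )

    # signal pools exclude substrate sites so kinase planting stays separate
    pp_substrate_all = set().union(*substrates.values())
    yp_substrate_all = set().union(*yp_substrates.values())
    wp_df, _ = _simulate_layer(rng, proteins, proteins[: cfg.n_proteins], truth,
                               cfg.k_true, cfg, samples, sample_to_line)
    pp_df, _ = _simulate_layer(rng, pp_features,
                               [f for f in pp_sites if f not in pp_substrate_all],
                               truth_super, 2, cfg, samples, sample_to_line)
    yp_df, _ = _simulate_layer(rng, yp_features,
                               [f for f in yp_sites if f not in yp_substrate_all],
                               truth, cfg.k_true, cfg, samples, sample_to_line)

    # planted differential kinase activity between the two super-groups
    planted_active: dict[str, int] = {}
    if cfg.planted_activity_delta != 0 and cfg.n_active > 0:
        picked = [kinases[i] for i in rng.choice(cfg.n_kinases, size=min(cfg.n_active, cfg.n_kinases), replace=False)]
        for i, kin in enumerate(sorted(picked)):
            favored = i % 2
            planted_active[kin] = favored
            cols = [smp for smp in samples if truth_super[sample_to_line[smp]] == favored]
            pp_rows = sorted((substrates[kin] | own_pp[kin]) & set(pp_df.index))
            yp_rows = sorted((yp_substrates[kin] | own_yp[kin]) & set(yp_df.index))
            pp_df.loc[pp_rows, cols] += cfg.planted_activity_delta
            yp_df.loc[yp_rows, cols] += cfg.planted_activity_delta

    # planted per-line outlier kinases
    planted_outliers: list[tuple[str, str]] = []
    if cfg.n_outliers > 0 and cfg.outlier_magnitude != 0:
        kin_pick = rng.choice(cfg.n_kinases, size=min(cfg.n_outliers, cfg.n_kinases), replace=False)
        line_pick = rng.choice(cfg.n_lines, size=min(cfg.n_outliers, cfg.n_lines), replace=False)
        for kin_i, line_i in zip(kin_pick, line_pick):
            kin, line = kinases[int(kin_i)], lines[int(line_i)]
            planted_outliers.append((kin, line))
            cols = [smp for smp in samples if sample_to_line[smp] == line]
            wp_df.loc[kin, cols] += cfg.outlier_magnitude
            pp_df.loc[sorted(own_pp[kin]), cols] += cfg.outlier_magnitude
            yp_df.loc[sorted(own_yp[kin]), cols] += cfg.outlier_magnitude

    batch = None
    if cfg.batch_shift != 0 and cfg.n_replicates > 1:
        batch = pd.Series({smp: f"B{int(smp.rsplit('_R', 1)[1])}" for smp in samples})
        shifted = [smp for smp in samples if batch[smp] != "B1"]
        for df in (wp_df, pp_df, yp_df):
            df[shifted] += cfg.batch_shift

    wp = OmicsMatrix("WP", wp_df, batch=batch)
    pp = OmicsMatrix("PP", pp_df, batch=None if batch is None else batch.copy())
    yp = OmicsMatrix("YP", yp_df, batch=None if batch is None else batch.copy())
    if cfg.dropout_rate > 0:
        wp = inject_missingness(wp, cfg.dropout_rate, cfg.dropout_bias, rng=rng)
        pp = inject_missingness(pp, cfg.dropout_rate, cfg.dropout_bias, rng=rng)
        yp = inject_missingness(yp, cfg.dropout_rate, cfg.dropout_bias, rng=rng)

    return SynthPanel(
        wp=wp, pp=pp, yp=yp,
        truth_labels=truth, truth_super=truth_super, sample_to_line=sample_to_line,
        ks_map=ks_map, site_to_protein=site_to_protein,
        planted_outliers=planted_outliers, planted_active_kinases=planted_active,
        config=cfg,
    )


def _fresh_position(rng: np.random.Generator, used: set[int]) -> int:
    while True:
        pos = int(rng.integers(1, 2000))
        if pos not in used:
            used.add(pos)
            return pos


def inject_missingness(
    matrix: OmicsMatrix,
    rate: float,
    bias: float = 0.0,
    rng: np.random.Generator | int | None = 0,
) -> OmicsMatrix:
    """Mask entries Bernoulli(rate) with logistic intensity dependence.

    Per-entry masking probability is ``rate * w / mean(w)`` with
    ``w = sigmoid(-bias * z)`` and z the globally standardized intensity, so
    the expected masked fraction is ``rate`` at any bias and low-intensity
    entries are preferentially masked when ``bias > 0``.
    """
    if not 0 <= rate < 1:
        raise ValueError(f"rate must be in [0, 1), got {rate}")
    if rate == 0:
        return matrix.copy()
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    X = matrix.values.copy()
    obs = ~np.isnan(X)
    z = np.zeros_like(X)
    mu, sd = np.nanmean(X), np.nanstd(X)
    if sd > 0:
        z[obs] = (X[obs] - mu) / sd
    w = 1.0 / (1.0 + np.exp(bias * z))
    w_mean = w[obs].mean()
    p = np.clip(rate * w / w_mean, 0.0, 1.0)
    mask = obs & (gen.random(X.shape) < p)
    X[mask] = np.nan
    return matrix.copy(data=pd.DataFrame(X, index=matrix.data.index, columns=matrix.data.columns))


def plant_outlier(matrix: OmicsMatrix, feature: str, sample: str, magnitude: float) -> OmicsMatrix:
    """Return a copy with one entry incremented by ``magnitude`` (log2)."""
    if feature not in matrix.data.index:
        raise KeyError(f"unknown feature {feature!r}")
    if sample not in matrix.data.columns:
        raise KeyError(f"unknown sample {sample!r}")
    out = matrix.copy()
    out.data.at[feature, sample] += magnitude
    return out


def write_panel(panel: SynthPanel, outdir) -> None:
    """Write the panel as plain TSV files plus truth and config files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_matrix(panel.wp, out / "wp.tsv")
    write_matrix(panel.pp, out / "pp.tsv")
    write_matrix(panel.yp, out / "yp.tsv")
    panel.truth_labels.rename("subtype").to_csv(out / "truth_subtype.tsv", sep="\t",
                                                index_label="line")
    panel.truth_super.rename("super_group").to_csv(out / "truth_super.tsv", sep="\t",
                                                   index_label="line")
    panel.sample_to_line.rename("line").to_csv(out / "samples.tsv", sep="\t",
                                               index_label="sample")
    panel.ks_map.to_frame().to_csv(out / "kinase_substrates.tsv", sep="\t", index=False)
    pd.Series(panel.site_to_protein, name="protein").to_csv(
        out / "site_to_protein.tsv", sep="\t", index_label="site")
    if panel.config is not None:
        with open(out / "config.txt", "w") as fh:
            for key, val in asdict(panel.config).items():
                fh.write(f"{key}\t{val}\n")
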