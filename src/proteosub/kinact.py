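"""Kinase activity inference and target nomination.

Three activity estimators are run on both the raw and the protein-normalized
phosphosite matrices, giving six differential-activity calls per kinase:

* mean fold difference — the mean log2 fold change of a kinase's substrate
  sites between two sample subgroups, with a one-sample t-test against 0;
* KSEA — the kinase-set enrichment z-statistic
  ``z = (mean_substrates - mean_background) * sqrt(m) / sd_background``;
* MLR — ridge-stabilized multilinear regression of the per-site fold-change
  vector on the site-by-kinase substrate design matrix.

A kinase is voted into a subgroup by a matrix when ``p < 0.05`` and
``|log2FC| > 1`` there; the 0-6 vote counts measure differential activity.
The module also provides an INKA-style per-sample kinase ranking (geometric
mean of kinase-centric and substrate-centric linear-intensity sums),
entry-level outlier-kinase detection (top 5% standardized intensities), and
two-group subset-specific hit calling for drug and dependency screens.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .matrix import OmicsMatrix, parse_site_key
from .stats import bh_adjust

#: p / |log2FC| thresholds for subset-specific hits
DRUG_PRESET = (0.05, 1.0)
DEPENDENCY_PRESET = (0.1, 2.0)

VOTE_P_THRESHOLD = 0.05
VOTE_FC_THRESHOLD = 1.0


@dataclass
class KinaseSubstrateMap:
    """Kinase -> substrate phosphosite keys, plus the kinase's own sites."""

    substrates: dict[str, set[str]] = field(default_factory=dict)
    own_sites: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.substrates = {k: set(v) for k, v in self.substrates.items()}
        self.own_sites = {k: set(v) for k, v in self.own_sites.items()}

    @property
    def kinases(self) -> list[str]:
        return sorted(set(self.substrates) | set(self.own_sites))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for kin in self.kinases:
            for s in sorted(self.substrates.get(kin, ())):
                rows.append((kin, s, "substrate"))
            for s in sorted(self.own_sites.get(kin, ())):
                rows.append((kin, s, "self"))
        out = pd.DataFrame(rows, columns=["kinase", "site", "relation"])
        key = out["site"].map(lambda s: parse_site_key(s))
        out["substrate_protein"] = [k.protein for k in key]
        out["residue"] = [k.residue for k in key]
        out["position"] = [k.position for k in key]
        return out[["kinase", "substrate_protein", "residue", "position", "relation", "site"]]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "KinaseSubstrateMap":
        """Build from a table with kinase, substrate_protein, residue, position, relation."""
        subs: dict[str, set[str]] = {}
        own: dict[str, set[str]] = {}
        for _, row in df.iterrows():
            site = f"{row['substrate_protein']}_{row['residue']}{int(row['position'])}"
            target = own if str(row.get("relation", "substrate")) == "self" else subs
            target.setdefault(str(row["kinase"]), set()).add(site)
        return cls(substrates=subs, own_sites=own)


# ---------------------------------------------------------------------------
# per-site statistics


def site_log2fc(
    matrix: OmicsMatrix | pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    test: str = "welch",
) -> pd.DataFrame:
    """Per-feature log2FC (mean A - mean B) and p-value between two groups.

    ``test`` is ``"welch"`` (default) or ``"wilcoxon"`` (rank-sum). With a
    single sample in a group the t-test is undefined; p is NaN and the row
    is flagged.
    """
    data = matrix.data if isinstance(matrix, OmicsMatrix) else matrix
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    A = data[list(group_a)].to_numpy()
    B = data[list(group_b)].to_numpy()
    fc = A.mean(axis=1) - B.mean(axis=1)
    if min(A.shape[1], B.shape[1]) < 2:
        p = np.full(len(fc), np.nan)
    elif test == "welch":
        with np.errstate(divide="ignore", invalid="ignore"):
            p = sps.ttest_ind(A, B, axis=1, equal_var=False).pvalue
    elif test == "wilcoxon":
        p = np.array([sps.ranksums(a, b).pvalue for a, b in zip(A, B)])
    else:
        raise ValueError(f"unknown test {test!r}")
    return pd.DataFrame(
        {"log2fc": fc, "p": p, "flagged": ~np.isfinite(p)}, index=data.index
    )


def _result_frame(rows: list[dict], method: str, source: str) -> pd.DataFrame:
    out = pd.DataFrame(rows).set_index("kinase") if rows else pd.DataFrame(
        columns=["activity", "log2fc", "p", "n_substrates"]
    )
    out.attrs["method"] = method
    out.attrs["input"] = source
    if len(out):
        out["p_adj"] = bh_adjust(out["p"].fillna(1.0).to_numpy())
    return out


# ---------------------------------------------------------------------------
# activity estimators (operate on a per-site stats table from site_log2fc)


def activity_mean_fd(
    site_stats: pd.DataFrame,
    ks_map: KinaseSubstrateMap,
    min_substrates: int = 3,
    source: str = "raw",
) -> pd.DataFrame:
    """Kinase activity as the mean substrate log2FC; one-sample t-test vs 0."""
    rows = []
    for kin in ks_map.kinases:
        subs = sorted(ks_map.substrates.get(kin, ()) & set(site_stats.index))
        if len(subs) < min_substrates:
            continue
        fcs = site_stats.loc[subs, "log2fc"].to_numpy()
        mean = float(fcs.mean())
        p = float(sps.ttest_1samp(fcs, 0.0).pvalue) if len(fcs) > 1 and fcs.std() > 0 else np.nan
        rows.append({"kinase": kin, "activity": mean, "log2fc": mean, "p": p,
                     "n_substrates": len(subs)})
    return _result_frame(rows, "meanFD", source)


def activity_ksea(
    site_stats: pd.DataFrame,
    ks_map: KinaseSubstrateMap,
    min_substrates: int = 3,
    source: str = "raw",
) -> pd.DataFrame:
    """Standard KSEA z-score against the background of all quantified sites."""
    bg = site_stats["log2fc"].to_numpy()
    mu_bg, sd_bg = float(bg.mean()), float(bg.std(ddof=1))
    rows = []
    for kin in ks_map.kinases:
        subs = sorted(ks_map.substrates.get(kin, ()) & set(site_stats.index))
        m = len(subs)
        if m < min_substrates:
            continue
        mean_sub = float(site_stats.loc[subs, "log2fc"].mean())
        if sd_bg == 0:
            z, p = np.nan, np.nan
        else:
            z = (mean_sub - mu_bg) * np.sqrt(m) / sd_bg
            p = float(2.0 * sps.norm.sf(abs(z)))
        rows.append({"kinase": kin, "activity": z, "log2fc": mean_sub, "p": p,
                     "n_substrates": m})
    return _result_frame(rows, "KSEA", source)


def activity_mlr(
    site_stats: pd.DataFrame,
    ks_map: KinaseSubstrateMap,
    ridge: float = 0.01,
    source: str = "raw",
) -> pd.DataFrame:
    """Multilinear regression of site fold changes on substrate membership.

    Solves ``min ||y - X beta||^2 + ridge * ||beta||^2`` where X[site, kinase]
    is 1 for annotated substrates; beta estimates each kinase's activity
    change. p-values come from the coefficient standard errors (t, df = n-q).
    Kinases with no annotated site in the data are omitted.
    """
    kinases = [k for k in ks_map.kinases
               if ks_map.substrates.get(k, set()) & set(site_stats.index)]
    if not kinases:
        return _result_frame([], "MLR", source)
    sites = sorted(set().union(*(ks_map.substrates[k] for k in kinases)) & set(site_stats.index))
    pos = {s: i for i, s in enumerate(sites)}
    X = np.zeros((len(sites), len(kinases)))
    for j, kin in enumerate(kinases):
        for s in ks_map.substrates[kin]:
            if s in pos:
                X[pos[s], j] = 1.0
    y = site_stats.loc[sites, "log2fc"].to_numpy()
    n, q = X.shape
    A = X.T @ X + ridge * np.eye(q)
    Ainv = np.linalg.inv(A)
    beta = Ainv @ X.T @ y
    resid = y - X @ beta
    df = max(n - q, 1)
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * (Ainv @ X.T @ X @ Ainv)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    p = 2.0 * sps.t.sf(np.abs(tvals), df)
    rows = [{"kinase": kin, "activity": float(beta[j]), "log2fc": float(beta[j]),
             "p": float(p[j]) if np.isfinite(p[j]) else np.nan,
             "n_substrates": int(X[:, j].sum())}
            for j, kin in enumerate(kinases)]
    return _result_frame(rows, "MLR", source)


# ---------------------------------------------------------------------------
# six-matrix voting


def differential_activity_votes(
    raw_pp: OmicsMatrix,
    normalized_pp: OmicsMatrix,
    group_a: list[str],
    group_b: list[str],
    ks_map: KinaseSubstrateMap,
    min_substrates: int = 3,
    p_threshold: float = VOTE_P_THRESHOLD,
    fc_threshold: float = VOTE_FC_THRESHOLD,
) -> pd.DataFrame:
    """Vote each kinase into subgroup S1 (A-high) or S2 across six matrices.

    The six activity tables come from {raw, protein-normalized} x
    {meanFD, KSEA, MLR}. A table votes S1 when p < 0.05 and log2FC > 1,
    S2 when p < 0.05 and log2FC < -1; otherwise it abstains. Raw p-values
    gate the vote; BH-adjusted values are carried in each activity table.
    """
    tables = activity_matrices(raw_pp, normalized_pp, group_a, group_b, ks_map, min_substrates)
    votes = pd.DataFrame(
        0, index=ks_map.kinases, columns=["votes_s1", "votes_s2"], dtype=int
    )
    for tab in tables:
        sig = tab[tab["p"] < p_threshold]
        up = sig[sig["log2fc"] > fc_threshold].index
        down = sig[sig["log2fc"] < -fc_threshold].index
        votes.loc[votes.index.intersection(up), "votes_s1"] += 1
        votes.loc[votes.index.intersection(down), "votes_s2"] += 1
    votes["votes_total"] = votes["votes_s1"] + votes["votes_s2"]
    votes.index.name = "kinase"
    return votes


def activity_matrices(
    raw_pp: OmicsMatrix,
    normalized_pp: OmicsMatrix,
    group_a: list[str],
    group_b: list[str],
    ks_map: KinaseSubstrateMap,
    min_substrates: int = 3,
) -> list[pd.DataFrame]:
    """The six (input, method) activity tables underlying the vote."""
    out = []
    for source, mat in (("raw", raw_pp), ("normalized", normalized_pp)):
        stats = site_log2fc(mat, group_a, group_b)
        out.append(activity_mean_fd(stats, ks_map, min_substrates, source))
        out.append(activity_ksea(stats, ks_map, min_substrates, source))
        out.append(activity_mlr(stats, ks_map, source=source))
    return out


# ---------------------------------------------------------------------------
# INKA-style per-sample ranking


def inka_score(
    yp_matrix: OmicsMatrix,
    ks_map: KinaseSubstrateMap,
    top_n: int = 10,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Per-sample kinase activity scores from phosphotyrosine evidence.

    For each sample, the kinase-centric arm C sums the linear-scale
    intensities of the kinase's own sites and the substrate arm S those of
    its substrates (missing -> 0); the score is ``sqrt(C * S)``, zero when
    either arm is silent. Returns the sample x kinase score table and the
    per-sample top-``top_n`` lists (ties broken by kinase id).
    """
    linear = (2.0 ** yp_matrix.data).fillna(0.0)
    present = set(yp_matrix.feature_keys)
    scores = {}
    for kin in ks_map.kinases:
        own = sorted(ks_map.own_sites.get(kin, ()) & present)
        subs = sorted(ks_map.substrates.get(kin, ()) & present)
        if not own and not subs:
            continue
        C = linear.loc[own].sum(axis=0) if own else pd.Series(0.0, index=linear.columns)
        S = linear.loc[subs].sum(axis=0) if subs else pd.Series(0.0, index=linear.columns)
        scores[kin] = np.sqrt(C * S)
    if not scores:
        raise ValueError("no kinase has any site in the matrix")
    table = pd.DataFrame(scores)  # samples x kinases
    table.index.name = "sample"
    top = {}
    for sample in table.index:
        row = table.loc[sample]
        ranked = sorted(row.index, key=lambda k: (-row[k], k))
        top[str(sample)] = [k for k in ranked[:top_n] if row[k] > 0]
    return table, top


# ---------------------------------------------------------------------------
# outlier kinases


def detect_outlier_kinases(
    matrices: dict[str, OmicsMatrix],
    feature_to_kinase: dict[str, dict[str, str]],
    top_frac: float = 0.05,
) -> pd.DataFrame:
    """Flag extreme (feature, sample) intensities mapping to kinases.

    Within each layer every entry is standardized across samples within its
    feature (rows with zero spread are excluded); entries above the layer's
    ``1 - top_frac`` z-quantile are flagged, and flags on kinase-annotated
    features are reported as candidate outlier kinases. Columns: kinase,
    layer, sample, feature, z.
    """
    if not 0 < top_frac < 1:
        raise ValueError(f"top_frac must be in (0, 1), got {top_frac}")
    rows = []
    for layer, mat in matrices.items():
        X = mat.values
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, ddof=1, keepdims=True)
        ok = (sd > 0).ravel()
        if not ok.any():
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            Z = (X - mu) / sd
        z_pool = Z[ok].ravel()
        cut = float(np.quantile(z_pool, 1.0 - top_frac))
        fmap = feature_to_kinase.get(layer, {})
        feats = np.array(mat.feature_keys)
        samples = np.array(mat.sample_ids)
        hit_r, hit_c = np.where((Z > cut) & ok[:, None])
        for r, c in zip(hit_r, hit_c):
            kin = fmap.get(feats[r])
            if kin is None:
                continue
            rows.append({"kinase": kin, "layer": layer, "sample": samples[c],
                         "feature": feats[r], "z": float(Z[r, c])})
    out = pd.DataFrame(rows, columns=["kinase", "layer", "sample", "feature", "z"])
    return out.sort_values(["layer", "kinase", "sample"]).reset_index(drop=True)


def outlier_kinase_union(flags: pd.DataFrame) -> list[str]:
    """Deduplicated kinases flagged in any layer."""
    return sorted(flags["kinase"].unique())


# ---------------------------------------------------------------------------
# subset-specific hits (drug response / genetic dependency)


def subset_specific_hits(
    values: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    p_threshold: float = DRUG_PRESET[0],
    fc_threshold: float = DRUG_PRESET[1],
) -> pd.DataFrame:
    """Two-group screen calls: S1-specific / S2-specific / equal per item.

    Welch p and log2FC (mean A - mean B) per row; an item is subset-specific
    when ``p < p_threshold`` and ``|log2FC| > fc_threshold`` (drug preset
    0.05/1, dependency preset 0.1/2). Constant items have undefined p and
    are labeled equal.
    """
    if min(len(group_a), len(group_b)) < 2:
        raise ValueError("both groups need >= 2 samples")
    stats = site_log2fc(values, group_a, group_b)
    call = np.where(
        (stats["p"] < p_threshold) & (stats["log2fc"] > fc_threshold), "S1-specific",
        np.where((stats["p"] < p_threshold) & (stats["log2fc"] < -fc_threshold),
                 "S2-specific", "equal"),
    )
    out = stats.copy()
    out["call"] = call
    out.loc[~np.isfinite(out["p"]), "call"] = "equal"
    return out
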