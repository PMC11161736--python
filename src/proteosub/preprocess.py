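"""Preprocessing for log2 omics matrices.

Covers the standard proteomics preparation chain: quantile normalization
(tolerant of missing values), missing-value imputation (down-shifted normal
or correlation-kNN), replicate correlation QC, phosphopeptide-to-phosphosite
collapse, protein-level normalization of phosphosites, per-batch centering,
and variability (MAD) filtering.

Conventions
-----------
* All intensities are log2 unless a function says otherwise; the peptide
  collapse sums on the linear scale and re-logs.
* "MAD" here defaults to the mean absolute deviation from the feature mean
  (``center="mean"``); the median-based variant is available via
  ``center="median"``.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .matrix import OmicsMatrix, parse_site_key


# ---------------------------------------------------------------------------
# quantile normalization


def quantile_normalize(matrix: OmicsMatrix) -> OmicsMatrix:
    """Quantile-normalize samples to a common reference distribution.

    The reference is the mean of the samples' sorted values. With missing
    values, each sample's non-missing values are ranked against the reference
    by interpolation at their fractional ranks (ties share the mean reference
    value), so complete matrices reduce to classic quantile normalization.
    """
    if matrix.n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    X = matrix.values.astype(float)
    n = X.shape[0]
    grid = np.linspace(0.0, 1.0, n)
    cols = []
    for j in range(X.shape[1]):
        obs = np.sort(X[~np.isnan(X[:, j]), j])
        if obs.size == 0:
            raise ValueError(f"sample {matrix.sample_ids[j]!r} has no observed values")
        q = np.linspace(0.0, 1.0, obs.size)
        cols.append(np.interp(grid, q, obs))
    reference = np.mean(cols, axis=0)

    out = X.copy()
    for j in range(X.shape[1]):
        mask = ~np.isnan(X[:, j])
        vals = X[mask, j]
        m = vals.size
        # average fractional ranks -> interpolate reference; ties share a value
        ranks = sps.rankdata(vals, method="average") - 1.0
        frac = ranks / (m - 1) if m > 1 else np.array([0.5])
        out[mask, j] = np.interp(frac, grid, reference)
    return matrix.copy(data=pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns))


# ---------------------------------------------------------------------------
# imputation


def impute(
    matrix: OmicsMatrix,
    method: str = "downshift",
    *,
    shift: float = 1.8,
    width: float = 0.3,
    k: int = 5,
    drop_all_missing: bool = False,
    rng: np.random.Generator | int | None = 0,
) -> OmicsMatrix:
    """Fill missing values.

    ``downshift`` draws each missing cell from ``Normal(mean_j - shift*sd_j,
    (width*sd_j)^2)`` of its sample — the usual proteomics model for
    left-censored missingness. ``knn`` averages, per missing cell, the values
    of the ``k`` most correlated features observed in that sample.
    Features missing everywhere raise unless ``drop_all_missing``.
    """
    data = matrix.data.copy()
    all_missing = data.isna().all(axis=1)
    if all_missing.any():
        if not drop_all_missing:
            raise ValueError(
                f"{int(all_missing.sum())} features are entirely missing; "
                "pass drop_all_missing=True to drop them"
            )
        data = data.loc[~all_missing]
    if not data.isna().any().any():
        return matrix.copy(data=data)

    if method == "downshift":
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        X = data.to_numpy()
        for j in range(X.shape[1]):
            col = X[:, j]
            miss = np.isnan(col)
            if not miss.any():
                continue
            mu, sd = np.nanmean(col), np.nanstd(col, ddof=1)
            if not np.isfinite(sd) or sd == 0:
                sd = 1.0
            col[miss] = gen.normal(mu - shift * sd, width * sd, size=int(miss.sum()))
        out = pd.DataFrame(X, index=data.index, columns=data.columns)
    elif method == "knn":
        out = _impute_knn(data, k=k)
    else:
        raise ValueError(f"unknown imputation method {method!r}")
    return matrix.copy(data=out)


def _impute_knn(data: pd.DataFrame, k: int) -> pd.DataFrame:
    X = data.to_numpy()
    # feature-feature Pearson correlation on pairwise-complete samples
    corr = pd.DataFrame(X.T).corr(min_periods=2).to_numpy()
    np.fill_diagonal(corr, -np.inf)
    corr = np.nan_to_num(corr, nan=-np.inf)
    out = X.copy()
    miss_rows = np.where(np.isnan(X).any(axis=1))[0]
    for i in miss_rows:
        order = np.argsort(-corr[i])
        for j in np.where(np.isnan(X[i]))[0]:
            donors = [f for f in order if np.isfinite(corr[i, f]) and not np.isnan(X[f, j])]
            if not donors:
                # no correlated donor observed here: fall back to feature mean
                out[i, j] = np.nanmean(X[i])
                continue
            out[i, j] = float(np.mean([X[f, j] for f in donors[:k]]))
    return pd.DataFrame(out, index=data.index, columns=data.columns)


# ---------------------------------------------------------------------------
# replicate QC


def replicate_correlation_qc(
    matrix: OmicsMatrix,
    sample_to_line: dict[str, str] | pd.Series,
    threshold: float = 0.8,
) -> pd.DataFrame:
    """Pairwise Pearson r between replicates of each line.

    Returns one row per replicate pair with the line, the two sample ids,
    r on shared non-missing features, the feature count, and a ``flagged``
    column (r below ``threshold`` or undefined).
    """
    s2l = pd.Series(sample_to_line)
    rows = []
    for line, group in s2l.groupby(s2l):
        reps = [s for s in group.index if s in matrix.data.columns]
        for a_i in range(len(reps)):
            for b_i in range(a_i + 1, len(reps)):
                a, b = reps[a_i], reps[b_i]
                x, y = matrix.data[a], matrix.data[b]
                ok = x.notna() & y.notna()
                n_shared = int(ok.sum())
                if n_shared < 2 or x[ok].std() == 0 or y[ok].std() == 0:
                    r = float("nan")
                else:
                    r = float(np.corrcoef(x[ok], y[ok])[0, 1])
                rows.append(
                    {"line": line, "sample_a": a, "sample_b": b, "r": r,
                     "n_features": n_shared,
                     "flagged": bool(not math.isfinite(r) or r < threshold)}
                )
    if not rows:
        raise ValueError("no line has >= 2 replicates")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# peptide -> site collapse


def collapse_peptides_to_sites(
    peptide_abundance: pd.DataFrame,
    peptide_to_sites: dict[str, list[str]],
    layer: str = "PP",
    *,
    input_scale: str = "linear",
) -> tuple[OmicsMatrix, int]:
    """Collapse a peptide x sample table to a phosphosite-centric matrix.

    Every peptide covering a site contributes its full linear-scale abundance
    to that site (a multiply-phosphorylated peptide counts toward each of its
    sites); sums are re-logged. Returns the site matrix and the number of
    peptides dropped for lacking a site annotation.

    ``input_scale`` is ``"linear"`` or ``"log2"`` (de-logged before summing).
    """
    ab = peptide_abundance.astype(float)
    if input_scale == "log2":
        ab = 2.0 ** ab
    elif input_scale != "linear":
        raise ValueError("input_scale must be 'linear' or 'log2'")
    site_sums: dict[str, np.ndarray] = {}
    dropped = 0
    for pep in ab.index:
        sites = peptide_to_sites.get(str(pep), [])
        if not sites:
            dropped += 1
            continue
        row = np.nan_to_num(ab.loc[pep].to_numpy(), nan=0.0)
        for s in sites:
            parse_site_key(s)
            site_sums[s] = site_sums.get(s, 0.0) + row
    if dropped:
        warnings.warn(f"{dropped} peptides had no site annotation and were dropped")
    if not site_sums:
        raise ValueError("no peptide mapped to any site")
    linear = pd.DataFrame(site_sums, index=ab.columns).T
    with np.errstate(divide="ignore"):
        logged = np.log2(linear.where(linear > 0))
    return OmicsMatrix(layer=layer, data=logged), dropped


def normalize_sites_by_protein(
    site_matrix: OmicsMatrix,
    protein_matrix: OmicsMatrix,
    site_to_protein: dict[str, str] | None = None,
) -> tuple[OmicsMatrix, int]:
    """Protein-normalized site intensities: log2(site) - log2(protein).

    Sites whose protein is absent from the protein matrix are dropped (the
    count is returned). A missing protein value makes the ratio missing.
    By default the host protein is taken from the site key itself.
    """
    keep, host = [], []
    for key in site_matrix.feature_keys:
        prot = site_to_protein.get(key) if site_to_protein else parse_site_key(key).protein
        if prot is not None and prot in protein_matrix.data.index:
            keep.append(key)
            host.append(prot)
    dropped = site_matrix.n_features - len(keep)
    if not keep:
        raise ValueError("no site maps to a protein in the protein matrix")
    shared = [s for s in site_matrix.sample_ids if s in protein_matrix.data.columns]
    site = site_matrix.data.loc[keep, shared]
    prot = protein_matrix.data.loc[host, shared]
    ratio = site.to_numpy() - prot.to_numpy()
    out = pd.DataFrame(ratio, index=keep, columns=shared)
    return site_matrix.copy(data=out), dropped


# ---------------------------------------------------------------------------
# batch centering and MAD filter


def center_batches(matrix: OmicsMatrix) -> OmicsMatrix:
    """Subtract each batch's per-feature median (no-op without batch labels)."""
    if matrix.batch is None:
        return matrix.copy()
    data = matrix.data.copy()
    for batch, group in matrix.batch.groupby(matrix.batch):
        cols = [c for c in group.index if c in data.columns]
        med = data[cols].median(axis=1)
        data[cols] = data[cols].sub(med, axis=0)
    return matrix.copy(data=data)


def feature_mad(matrix: OmicsMatrix, center: str = "mean") -> pd.Series:
    """Per-feature absolute deviation across samples (mean- or median-based)."""
    if center == "mean":
        dev = matrix.data.sub(matrix.data.mean(axis=1), axis=0).abs()
        return dev.mean(axis=1)
    if center == "median":
        dev = matrix.data.sub(matrix.data.median(axis=1), axis=0).abs()
        return dev.median(axis=1)
    raise ValueError("center must be 'mean' or 'median'")


def mad_filter(matrix: OmicsMatrix, fraction: float, center: str = "mean") -> OmicsMatrix:
    """Keep the top ``ceil(fraction * n)`` most variable features by MAD.

    Ties are broken by feature key order, so the retained set is
    deterministic and nested across fractions.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    mad = feature_mad(matrix, center=center)
    n_keep = math.ceil(fraction * matrix.n_features)
    order = sorted(matrix.feature_keys, key=lambda f: (-mad[f], f))
    pos = {f: i for i, f in enumerate(matrix.feature_keys)}
    kept = sorted(order[:n_keep], key=pos.__getitem__)
    return matrix.copy(data=matrix.data.loc[kept])
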