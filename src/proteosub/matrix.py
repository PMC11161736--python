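"""Omics matrix container and TSV round-trip I/O.

The universal carrier is :class:`OmicsMatrix`: a features x samples table of
log2 intensities with a layer tag (``WP`` whole proteome, ``PP`` global
phosphoproteome, ``YP`` phosphotyrosine). Missing values are ``NaN``.
Phosphosite features use keys of the form ``PROTEIN_S123`` / ``_T45`` /
``_Y99`` (residue letter + 1-based position, appended to the protein id
with an underscore).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

LAYERS = ("WP", "PP", "YP")

_SITE_RE = re.compile(r"^(?P<protein>.+)_(?P<residue>[STY])(?P<position>\d+)$")


class PhosphoSiteKey(NamedTuple):
    """Parsed phosphosite identifier: protein, residue (S/T/Y), 1-based position."""

    protein: str
    residue: str
    position: int

    def __str__(self) -> str:  # pragma: no cover - trivial
        return f"{self.protein}_{self.residue}{self.position}"


def parse_site_key(key: str, layer: str | None = None) -> PhosphoSiteKey:
    """Parse ``PROT_S123``-style keys; YP keys must carry residue Y."""
    m = _SITE_RE.match(key)
    if m is None:
        raise ValueError(f"malformed phosphosite key: {key!r}")
    site = PhosphoSiteKey(m["protein"], m["residue"], int(m["position"]))
    if site.position < 1:
        raise ValueError(f"phosphosite position must be >= 1: {key!r}")
    if layer == "YP" and site.residue != "Y":
        raise ValueError(f"YP feature {key!r} does not carry a tyrosine residue")
    return site


@dataclass
class OmicsMatrix:
    """Features x samples log2 intensity matrix for one omic layer.

    Parameters
    ----------
    layer : {"WP", "PP", "YP"}
    data : DataFrame, features as index, sample ids as columns, NaN = missing.
    batch : optional mapping sample id -> batch label.
    """

    layer: str
    data: pd.DataFrame
    batch: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"layer must be one of {LAYERS}, got {self.layer!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature keys: {dups[:5]}")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        self.data = self.data.astype(float)
        if self.layer in ("PP", "YP"):
            for key in self.data.index:
                parse_site_key(str(key), self.layer)

    @property
    def feature_keys(self) -> list[str]:
        return [str(k) for k in self.data.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def is_complete(self) -> bool:
        return not self.data.isna().any().any()

    def missing_mask(self) -> pd.DataFrame:
        return self.data.isna()

    def copy(self, data: pd.DataFrame | None = None) -> "OmicsMatrix":
        return OmicsMatrix(
            layer=self.layer,
            data=self.data.copy() if data is None else data,
            batch=None if self.batch is None else self.batch.copy(),
        )

    def shifted_nonnegative(self) -> pd.DataFrame:
        """Data shifted by the global minimum so all entries are >= 0."""
        lo = np.nanmin(self.data.to_numpy())
        return self.data - min(lo, 0.0)


def read_matrix(path, layer: str) -> OmicsMatrix:
    """Read a TSV matrix (first column = feature key, header = sample ids).

    Empty cells and ``NA`` markers are missing; any other non-numeric cell
    raises with the offending row and column named.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    cleaned = raw.apply(lambda s: s.str.strip()).replace({"": np.nan, "NA": np.nan, "NaN": np.nan, "nan": np.nan})
    out = cleaned.apply(pd.to_numeric, errors="coerce")
    bad = out.isna() & cleaned.notna()
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell {raw.iat[r, c]!r} at feature {raw.index[r]!r}, sample {raw.columns[c]!r}"
        )
    out.index.name = None
    return OmicsMatrix(layer=layer, data=out)


def write_matrix(matrix: OmicsMatrix, path) -> None:
    """Write TSV with ``NA`` for missing entries; round-trips with read_matrix."""
    matrix.data.to_csv(path, sep="\t", na_rep="NA", index_label="feature", float_format="%.10g")
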