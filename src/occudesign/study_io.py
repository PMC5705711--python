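"""Reading, validating, pooling and writing detection histories and covariates.

A detection history is a sites x occasions matrix with entries 0
(surveyed, not detected), 1 (detected) or missing (site not visited on
that occasion).  Missing visits are the norm in ragged monthly designs
where the number of consecutive survey nights varies between months, so
the container carries an explicit missing sentinel (NaN internally,
``NA`` on disk) rather than overloading 0.

File formats
------------
* Detection history: CSV with header ``site,occ_1,...,occ_K`` and cell
  values in ``{0, 1, NA}``.
* Site covariates: CSV keyed by ``site``, one row per site.
* Survey covariates: long CSV keyed by ``site,occ`` with one column per
  covariate; a cell may be ``NA`` only where the paired history entry is
  missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DetectionHistory",
    "SiteCovariateTable",
    "SurveyCovariateTable",
    "read_history",
    "write_history",
    "read_site_covariates",
    "write_site_covariates",
    "read_survey_covariates",
    "write_survey_covariates",
    "pool_tagged_and_neighbour",
    "concat_periods",
]


class ValidationError(ValueError):
    """A table violates a structural invariant of the study design."""


@dataclass
class DetectionHistory:
    """Sites x occasions detection/non-detection matrix.

    Parameters
    ----------
    site_ids
        Unique site identifiers, one per matrix row.
    matrix
        Float array of shape ``(n_sites, n_occasions)`` with entries in
        ``{0.0, 1.0, nan}``; ``nan`` marks a missing visit.
    occasion_labels
        Unique occasion labels, one per column (e.g. ``feb_1``).
    """

    site_ids: list[str]
    matrix: np.ndarray
    occasion_labels: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValidationError("detection matrix must be 2-dimensional")
        self.site_ids = [str(s) for s in self.site_ids]
        if self.occasion_labels is None:
            self.occasion_labels = [f"occ_{j + 1}" for j in range(self.matrix.shape[1])]
        self.occasion_labels = [str(c) for c in self.occasion_labels]
        if len(self.site_ids) != self.matrix.shape[0]:
            raise ValidationError("site_ids length does not match matrix rows")
        if len(self.occasion_labels) != self.matrix.shape[1]:
            raise ValidationError("occasion_labels length does not match matrix columns")
        if len(set(self.site_ids)) != len(self.site_ids):
            dup = sorted({s for s in self.site_ids if self.site_ids.count(s) > 1})
            raise ValidationError(f"duplicate site ids: {dup}")
        if len(set(self.occasion_labels)) != len(self.occasion_labels):
            raise ValidationError("duplicate occasion labels")
        observed = self.matrix[~np.isnan(self.matrix)]
        bad = observed[(observed != 0.0) & (observed != 1.0)]
        if bad.size:
            raise ValidationError(
                f"history entries must be 0, 1 or missing; found {sorted(set(bad.tolist()))}"
            )

    # ------------------------------------------------------------------
    @property
    def n_sites(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.matrix.shape[1]

    @property
    def observed_mask(self) -> np.ndarray:
        """Boolean mask of surveyed (non-missing) cells."""
        return ~np.isnan(self.matrix)

    def n_detections(self) -> np.ndarray:
        """Per-site number of occasions with a detection."""
        return np.nansum(self.matrix, axis=1).astype(int)

    def n_visits(self) -> np.ndarray:
        """Per-site number of non-missing occasions."""
        return self.observed_mask.sum(axis=1)

    def naive_occupancy(self) -> float:
        """Fraction of sites with at least one detection (no detection correction)."""
        return float(np.mean(self.n_detections() > 0))

    def require_observed_rows(self) -> None:
        """Raise if any site was never visited (all-missing row)."""
        empty = np.where(self.n_visits() == 0)[0]
        if empty.size:
            ids = [self.site_ids[i] for i in empty]
            raise ValidationError(f"sites with no observed occasion: {ids}")


@dataclass
class SiteCovariateTable:
    """One row of site-level covariates per site, keyed by site id.

    ``table`` is indexed by site id; typical columns are ``elevation``
    (m a.s.l.), ``zone`` (low/medium/high), ``bromeliad_size`` and
    ``rosette_volume`` (height x width products), ``n_leaves`` and
    ``n_neighbours`` (counts).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValidationError("duplicate site ids in site covariate table")
        self.table.index = self.table.index.astype(str)
        for col in ("n_leaves", "n_neighbours"):
            if col in self.table.columns and (self.table[col].dropna() < 0).any():
                raise ValidationError(f"negative values in count covariate {col!r}")

    def aligned_to(self, history: DetectionHistory) -> pd.DataFrame:
        missing = [s for s in history.site_ids if s not in self.table.index]
        if missing:
            raise ValidationError(f"sites absent from covariate table: {missing}")
        return self.table.loc[history.site_ids]

    @property
    def columns(self) -> list[str]:
        return list(self.table.columns)


@dataclass
class SurveyCovariateTable:
    """Survey-level (site x occasion) covariates.

    Each covariate is a full sites x occasions array aligned with the
    paired :class:`DetectionHistory`; object dtype holds categorical
    levels (e.g. observer experience), float dtype holds continuous
    values (e.g. minutes after dusk).  A cell may be missing only where
    the corresponding history entry is missing.
    """

    site_ids: list[str]
    occasion_labels: list[str]
    covariates: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.site_ids = [str(s) for s in self.site_ids]
        self.occasion_labels = [str(c) for c in self.occasion_labels]
        shape = (len(self.site_ids), len(self.occasion_labels))
        for name, arr in self.covariates.items():
            arr = np.asarray(arr)
            if arr.shape != shape:
                raise ValidationError(
                    f"survey covariate {name!r} has shape {arr.shape}, expected {shape}"
                )
            self.covariates[name] = arr

    @property
    def columns(self) -> list[str]:
        return list(self.covariates.keys())

    def check_against(self, history: DetectionHistory) -> None:
        if self.site_ids != history.site_ids or self.occasion_labels != history.occasion_labels:
            raise ValidationError("survey covariates not aligned with detection history")
        for name, arr in self.covariates.items():
            if arr.dtype.kind == "f":
                miss = np.isnan(arr)
            else:
                miss = pd.isna(arr)
            bad = miss & history.observed_mask
            if bad.any():
                raise ValidationError(
                    f"survey covariate {name!r} missing at surveyed cells"
                )


# ----------------------------------------------------------------------
# readers / writers
# ----------------------------------------------------------------------

def _parse_cell(raw: object, site: str, col: str) -> float:
    if pd.isna(raw) or str(raw).strip().upper() in {"NA", ""}:
        return np.nan
    s = str(raw).strip()
    if s in {"0", "0.0"}:
        return 0.0
    if s in {"1", "1.0"}:
        return 1.0
    raise ValidationError(f"invalid history cell {raw!r} at site {site!r}, occasion {col!r}")


def read_history(path: str | Path, require_observed: bool = True) -> DetectionHistory:
    """Read a detection-history CSV (``site,occ_1,...,occ_K``; cells 0/1/NA)."""
    df = pd.read_csv(path, dtype=str)
    if df.columns[0] != "site":
        raise ValidationError(f"first column must be 'site', found {df.columns[0]!r}")
    occ_cols = list(df.columns[1:])
    if not occ_cols:
        raise ValidationError("history file has no occasion columns")
    sites = df["site"].tolist()
    matrix = np.empty((len(sites), len(occ_cols)))
    for i, site in enumerate(sites):
        for j, col in enumerate(occ_cols):
            matrix[i, j] = _parse_cell(df.iloc[i, j + 1], site, col)
    hist = DetectionHistory(sites, matrix, occ_cols)
    if require_observed:
        hist.require_observed_rows()
    return hist


def write_history(history: DetectionHistory, path: str | Path) -> None:
    """Write a detection history as CSV; missing cells become ``NA``."""
    safe = np.nan_to_num(history.matrix).astype(int).astype(str)
    cells = np.where(np.isnan(history.matrix), "NA", safe)
    df = pd.DataFrame(cells, columns=history.occasion_labels)
    df.insert(0, "site", history.site_ids)
    df.to_csv(path, index=False)


def read_site_covariates(path: str | Path) -> SiteCovariateTable:
    df = pd.read_csv(path)
    if "site" not in df.columns:
        raise ValidationError("site covariate file must have a 'site' column")
    return SiteCovariateTable(df.set_index("site"))


def write_site_covariates(covs: SiteCovariateTable, path: str | Path) -> None:
    covs.table.reset_index(names="site").to_csv(path, index=False, float_format="%.6g")


def read_survey_covariates(
    path: str | Path, site_ids: Sequence[str], occasion_labels: Sequence[str]
) -> SurveyCovariateTable:
    """Read long-format (``site,occ,<covariates...>``) survey covariates."""
    df = pd.read_csv(path, dtype={"site": str, "occ": str})
    for key in ("site", "occ"):
        if key not in df.columns:
            raise ValidationError(f"survey covariate file must have a {key!r} column")
    names = [c for c in df.columns if c not in ("site", "occ")]
    site_pos = {s: i for i, s in enumerate(map(str, site_ids))}
    occ_pos = {c: j for j, c in enumerate(map(str, occasion_labels))}
    covs: dict[str, np.ndarray] = {}
    for name in names:
        numeric = pd.to_numeric(df[name], errors="coerce")
        is_numeric = numeric.notna().sum() == df[name].notna().sum()
        if is_numeric:
            arr = np.full((len(site_pos), len(occ_pos)), np.nan)
        else:
            arr = np.full((len(site_pos), len(occ_pos)), None, dtype=object)
        covs[name] = arr
    for _, row in df.iterrows():
        if row["site"] not in site_pos or row["occ"] not in occ_pos:
            raise ValidationError(
                f"survey covariate row ({row['site']!r}, {row['occ']!r}) not in history"
            )
        i, j = site_pos[row["site"]], occ_pos[row["occ"]]
        for name in names:
            val = row[name]
            if covs[name].dtype.kind == "f":
                covs[name][i, j] = float(val) if not pd.isna(val) else np.nan
            else:
                covs[name][i, j] = None if pd.isna(val) else val
    return SurveyCovariateTable(list(map(str, site_ids)), list(map(str, occasion_labels)), covs)


def write_survey_covariates(covs: SurveyCovariateTable, path: str | Path) -> None:
    records = []
    for i, site in enumerate(covs.site_ids):
        for j, occ in enumerate(covs.occasion_labels):
            rec = {"site": site, "occ": occ}
            for name, arr in covs.covariates.items():
                rec[name] = arr[i, j]
            records.append(rec)
    pd.DataFrame(records).to_csv(path, index=False, float_format="%.6g")


# ----------------------------------------------------------------------
# pooling and concatenation
# ----------------------------------------------------------------------

def pool_tagged_and_neighbour(
    tagged: DetectionHistory, neighbour: DetectionHistory
) -> DetectionHistory:
    """Pool tagged-site and neighbouring-bromeliad histories into one record.

    A site-occasion is scored 1 if the species was seen in either the
    tagged bromeliad or any touching neighbour, 0 if at least one record
    is an observed absence and neither is a detection, and missing only
    when both records are missing.  An observed absence always outranks
    a missing visit because it carries information.
    """
    if tagged.site_ids != neighbour.site_ids:
        raise ValidationError("pooling requires identical site ids")
    if tagged.occasion_labels != neighbour.occasion_labels:
        raise ValidationError("pooling requires identical occasion labels")
    # fmax: NaN only when both NaN; otherwise max over observed entries
    pooled = np.fmax(tagged.matrix, neighbour.matrix)
    return DetectionHistory(list(tagged.site_ids), pooled, list(tagged.occasion_labels))


def concat_periods(
    histories: Sequence[DetectionHistory],
    period_labels: Sequence[str] | None = None,
) -> DetectionHistory:
    """Concatenate survey periods (e.g. monthly datasets) column-wise.

    Sites are the union across periods in order of first appearance;
    a site absent from a period receives all-missing columns there,
    which is how sites added partway through a study are represented.
    Occasion labels are prefixed by the period label.
    """
    if not histories:
        raise ValidationError("no histories to concatenate")
    if period_labels is None:
        period_labels = [f"p{i + 1}" for i in range(len(histories))]
    if len(period_labels) != len(histories):
        raise ValidationError("one period label per history required")

    all_sites: list[str] = []
    for h in histories:
        for s in h.site_ids:
            if s not in all_sites:
                all_sites.append(s)

    blocks = []
    labels: list[str] = []
    for h, plab in zip(histories, period_labels):
        block = np.full((len(all_sites), h.n_occasions), np.nan)
        pos = {s: i for i, s in enumerate(all_sites)}
        for i, s in enumerate(h.site_ids):
            block[pos[s]] = h.matrix[i]
        blocks.append(block)
        labels.extend(f"{plab}_{c}" for c in h.occasion_labels)
    return DetectionHistory(all_sites, np.hstack(blocks), labels)
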