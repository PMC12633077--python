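"""Per-feature cosinor analysis over a cohort table.

The cohort is a long-format table of cross-sectional measurements — one row
per (subject, group, clock time, feature, value) — covering the typical
circadian necropsy design: two genotype or colonization groups, six
timepoints at 4-hour intervals across the 24-h cycle (ZT2 … ZT22), a few
subjects per group per timepoint, each subject measured once.

``analyze_cohort`` fits the single cosinor per (feature, group) stratum,
runs the zero-amplitude test, and — when exactly two groups are present —
compares MESOR, amplitude, and acrophase between them, with
Benjamini–Hochberg adjustment applied across features within each test
family.  The result mirrors the familiar published layout: one row per
(feature, group) with zero-amplitude p, M ± SE, A ± SE, acrophase ± SE and
the three comparison p-values.  A companion table carries the per-timepoint
Student's t-tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compare import bh_adjust, compare_fits, timepoint_test
from .cosinor import (
    DEFAULT_PERIOD_H,
    CosinorFit,
    DesignError,
    InsufficientDataError,
    InvalidArgumentError,
    fit_single_cosinor,
    zero_amplitude_test,
)

__all__ = [
    "COHORT_COLUMNS",
    "RHYTHM_COLUMNS",
    "TIMEPOINT_COLUMNS",
    "SchemaError",
    "CohortTable",
    "parse_time_label",
    "load_cohort",
    "write_cohort",
    "analyze_cohort",
    "write_rhythm_table",
    "load_rhythm_table",
]

logger = logging.getLogger(__name__)

COHORT_COLUMNS = ["subject_id", "group", "time_h", "feature", "value"]

RHYTHM_COLUMNS = [
    "feature",
    "group",
    "n",
    "status",
    "zero_amplitude_p",
    "mesor",
    "mesor_se",
    "amplitude",
    "amplitude_se",
    "acrophase_h",
    "acrophase_se_h",
    "mesor_test_p",
    "amplitude_test_p",
    "acrophase_comparison_p",
    "zero_amplitude_p_adj",
    "mesor_test_p_adj",
    "amplitude_test_p_adj",
    "acrophase_comparison_p_adj",
]

TIMEPOINT_COLUMNS = ["feature", "time_h", "t", "p", "p_adj"]


class SchemaError(InvalidArgumentError):
    """An input file does not match the documented column schema."""


def parse_time_label(token: str | float) -> float:
    """Parse a time-of-day label into hours.

    Accepts plain hours (``"14"``, ``14.0``) and zeitgeber tokens
    (``"ZT2"``, ``"zt14.5"``): the ZT prefix is stripped and the remainder
    read as hours since lights-on.
    """
    if isinstance(token, (int, float)):
        return float(token)
    s = str(token).strip()
    if s[:2].upper() == "ZT":
        s = s[2:]
    try:
        return float(s)
    except ValueError as exc:
        raise InvalidArgumentError(f"cannot parse time label {token!r}") from exc


@dataclass
class CohortTable:
    """Long-format cohort of cross-sectional measurements.

    ``data`` holds one row per measurement with columns
    ``subject_id, group, time_h, feature, value``; ``n_dropped`` counts
    rows removed at load time for blank/missing values.
    """

    data: pd.DataFrame
    n_dropped: int = 0

    def __post_init__(self) -> None:
        missing = [c for c in COHORT_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"cohort table missing columns: {missing}")
        self.data = self.data[COHORT_COLUMNS].reset_index(drop=True)

    @property
    def groups(self) -> list[str]:
        return sorted(self.data["group"].unique())

    @property
    def features(self) -> list[str]:
        return sorted(self.data["feature"].unique())

    @property
    def timepoints(self) -> list[float]:
        return sorted(self.data["time_h"].unique())

    def design_summary(self) -> pd.DataFrame:
        """Subjects per (feature, group, timepoint) cell."""
        return (
            self.data.groupby(["feature", "group", "time_h"])
            .size()
            .rename("n")
            .reset_index()
        )


def load_cohort(path) -> CohortTable:
    """Read a long-format cohort TSV (UTF-8, '.' decimal, blank = missing).

    Rows with a blank/unparseable value are dropped with a logged count;
    time labels may be plain hours or ZT tokens.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise InvalidArgumentError(f"{path}: empty cohort table")

    df = df[COHORT_COLUMNS].copy()
    df["time_h"] = df["time_h"].map(parse_time_label)
    values = pd.to_numeric(df["value"].replace("", np.nan), errors="coerce")
    bad = values.isna()
    if bad.any():
        # +2: header line and 1-based numbering
        lines = [int(i) + 2 for i in np.flatnonzero(bad.to_numpy())]
        logger.info("dropped %d rows with missing values (lines %s)", bad.sum(), lines)
    df["value"] = values
    kept = df.loc[~bad].reset_index(drop=True)
    return CohortTable(data=kept, n_dropped=int(bad.sum()))


def write_cohort(cohort: CohortTable, path) -> None:
    """Write a cohort back to the canonical TSV schema."""
    out = cohort.data.copy()
    out["time_h"] = out["time_h"].map(_fmt_number)
    out["value"] = out["value"].map(_fmt_number)
    out.to_csv(path, sep="\t", index=False)


def _fmt_number(x: float) -> str:
    """Render a float compactly but losslessly (repr round-trips)."""
    if isinstance(x, float) and x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(float(x))


@dataclass
class CohortAnalysis:
    """Result bundle from :func:`analyze_cohort`."""

    rhythm: pd.DataFrame
    timepoint: pd.DataFrame
    fits: dict = field(default_factory=dict)  # (feature, group) -> CosinorFit


def _fit_stratum(sub: pd.DataFrame, period_h: float) -> tuple[CosinorFit | None, str]:
    try:
        fit = fit_single_cosinor(
            (sub["time_h"].to_numpy(), sub["value"].to_numpy()), period_h
        )
        return fit, "ok"
    except DesignError:
        return None, "insufficient design"
    except InsufficientDataError:
        return None, "insufficient data"


def analyze_cohort(
    cohort: CohortTable,
    period_h: float = DEFAULT_PERIOD_H,
    alpha: float = 0.05,
    pooled_t: bool = True,
) -> CohortAnalysis:
    """Run the full per-feature rhythm analysis.

    Per (feature, group): single-cosinor fit + zero-amplitude test.  With
    exactly two groups, the three parameter comparisons are added (same
    values on both group rows of a feature).  BH adjustment runs across
    features within each test family.  Strata with fewer than 3 distinct
    timepoints are reported with ``status`` set, never silently dropped.
    The companion timepoint table holds per-ZT two-group Student's t-tests,
    BH-adjusted across all its rows.
    """
    groups = cohort.groups
    two_groups = len(groups) == 2

    rows: list[dict] = []
    fits: dict[tuple[str, str], CosinorFit] = {}
    for feature in cohort.features:
        feat_df = cohort.data[cohort.data["feature"] == feature]
        for group in groups:
            sub = feat_df[feat_df["group"] == group]
            if len(sub) == 0:
                continue
            fit, status = _fit_stratum(sub, period_h)
            row: dict = {
                "feature": feature,
                "group": group,
                "n": len(sub),
                "status": status,
            }
            if fit is not None:
                fits[(feature, group)] = fit
                za = zero_amplitude_test(fit)
                row.update(
                    zero_amplitude_p=za.p,
                    mesor=fit.mesor,
                    mesor_se=fit.mesor_se,
                    amplitude=fit.amplitude,
                    amplitude_se=fit.amplitude_se,
                    acrophase_h=fit.acrophase_h,
                    acrophase_se_h=fit.acrophase_se_h,
                )
            rows.append(row)

        if two_groups and all((feature, g) in fits for g in groups):
            triple = compare_fits(fits[(feature, groups[0])], fits[(feature, groups[1])])
            comp = {
                "mesor_test_p": triple.mesor_test.p,
                "amplitude_test_p": triple.amplitude_test.p if triple.amplitude_test.defined else np.nan,
                "acrophase_comparison_p": triple.acrophase_test.p if triple.acrophase_test.defined else np.nan,
            }
            for row in rows:
                if row["feature"] == feature:
                    row.update(comp)

    rhythm = pd.DataFrame(rows)
    for col in RHYTHM_COLUMNS:
        if col not in rhythm.columns:
            rhythm[col] = np.nan
    rhythm = rhythm[RHYTHM_COLUMNS]

    # BH families: each family adjusted across features (per run)
    _adjust_family(rhythm, "zero_amplitude_p", "zero_amplitude_p_adj", per_feature=False)
    for fam in ("mesor_test_p", "amplitude_test_p", "acrophase_comparison_p"):
        _adjust_family(rhythm, fam, fam + "_adj", per_feature=True)

    timepoint = _timepoint_table(cohort, pooled_t) if two_groups else pd.DataFrame(
        columns=TIMEPOINT_COLUMNS
    )
    return CohortAnalysis(rhythm=rhythm, timepoint=timepoint, fits=fits)


def _adjust_family(rhythm: pd.DataFrame, col: str, adj_col: str, per_feature: bool) -> None:
    """BH-adjust one p-value family in place.

    Comparison families carry one p per feature duplicated on both group
    rows; adjust over unique features to avoid double counting.
    """
    if per_feature:
        sub = rhythm.drop_duplicates("feature")
        mask = sub[col].notna()
        if mask.any():
            adj = pd.Series(bh_adjust(sub.loc[mask, col].to_numpy()), index=sub.index[mask])
            by_feature = dict(zip(sub.loc[mask, "feature"], adj))
            rhythm[adj_col] = rhythm["feature"].map(by_feature)
    else:
        mask = rhythm[col].notna()
        if mask.any():
            rhythm.loc[mask, adj_col] = bh_adjust(rhythm.loc[mask, col].to_numpy())


def _timepoint_table(cohort: CohortTable, pooled: bool) -> pd.DataFrame:
    g1, g2 = cohort.groups
    rows = []
    for feature in cohort.features:
        feat_df = cohort.data[cohort.data["feature"] == feature]
        for t in sorted(feat_df["time_h"].unique()):
            v1 = feat_df.loc[(feat_df["group"] == g1) & (feat_df["time_h"] == t), "value"]
            v2 = feat_df.loc[(feat_df["group"] == g2) & (feat_df["time_h"] == t), "value"]
            if len(v1) < 2 or len(v2) < 2:
                continue
            res = timepoint_test(v1.to_numpy(), v2.to_numpy(), pooled=pooled)
            rows.append({"feature": feature, "time_h": t, "t": res.statistic, "p": res.p})
    tp = pd.DataFrame(rows, columns=TIMEPOINT_COLUMNS[:-1])
    if len(tp):
        tp["p_adj"] = bh_adjust(tp["p"].to_numpy())
    else:
        tp["p_adj"] = pd.Series(dtype=float)
    return tp


def write_rhythm_table(rhythm: pd.DataFrame, path) -> None:
    """Write the rhythm table as TSV with fixed column order.

    Undefined quantities (e.g. acrophase of a flat fit, comparison columns
    of a single-group run) render as empty cells, never the string 'nan'.
    """
    if len(rhythm) == 0:
        raise InvalidArgumentError("refusing to write an empty rhythm table")
    out = rhythm[RHYTHM_COLUMNS].copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(lambda x: "" if pd.isna(x) else _fmt_number(x))
    out.to_csv(path, sep="\t", index=False)


def load_rhythm_table(path) -> pd.DataFrame:
    """Load a rhythm table written by :func:`write_rhythm_table`."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in RHYTHM_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    return df[RHYTHM_COLUMNS]
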