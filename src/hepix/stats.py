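"""Cohort-level statistics on per-pixel entropy.

Covers TNM-to-stage mapping, area-weighted resampling of entropy values,
Welch's t-test, histogramming and Jensen-Shannon divergence, and the tidy
cancer-vs-noncancer comparison report.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from hepix.errors import (
    ConfigError,
    DataError,
    EmptyStratumError,
    InsufficientDataError,
)

logger = logging.getLogger(__name__)

STAGES = ("I", "II", "III", "IV-A", "IV-B")
UNKNOWN_STAGE = "Unknown"
REGION_CLASSES = ("cancer", "noncancer")

COHORT_COLUMNS = [
    "specimen_id",
    "cohort",
    "T",
    "N",
    "M",
    "stage",
    "tissue_area_cancer",
    "tissue_area_noncancer",
]


# ---------------------------------------------------------------------------
# stage mapping
# ---------------------------------------------------------------------------

_T_VALUES = ("T1", "T2", "T3", "T4")
_N_VALUES = ("N0", "N1")
_M_VALUES = ("M0", "M1")


def _normalize(code, prefix: str, allowed: tuple[str, ...]) -> str | None:
    """Normalize a TNM field ('T2', '2', 't2') to canonical form, or None."""
    if code is None:
        return None
    if isinstance(code, float) and math.isnan(code):
        return None
    text = str(code).strip().upper()
    if not text:
        return None
    if re.fullmatch(r"\d+", text):
        text = prefix + text
    return text if text in allowed else None


def default_stage_table() -> dict[tuple[str, str, str], str]:
    """Stage lookup for every complete (T, N, M) combination.

    Rules (intrahepatic cholangiocarcinoma, UICC 7th edition): M1 -> IV-B;
    else T4 or N1 -> IV-A; else T3/N0 -> III; T2/N0 -> II; T1/N0 -> I.
    """
    table: dict[tuple[str, str, str], str] = {}
    for t in _T_VALUES:
        for n in _N_VALUES:
            for m in _M_VALUES:
                if m == "M1":
                    stage = "IV-B"
                elif t == "T4" or n == "N1":
                    stage = "IV-A"
                else:
                    stage = {"T1": "I", "T2": "II", "T3": "III"}[t]
                table[(t, n, m)] = stage
    return table


def map_tnm_to_stage(
    T, N, M, stage_table: dict[tuple[str, str, str], str] | None = None
) -> str:
    """Map a TNM triplet to a stage via a configurable lookup table.

    Any missing or unrecognized field yields ``"Unknown"``; this never raises.
    """
    table = stage_table if stage_table is not None else default_stage_table()
    t = _normalize(T, "T", _T_VALUES)
    n = _normalize(N, "N", _N_VALUES)
    m = _normalize(M, "M", _M_VALUES)
    if t is None or n is None or m is None:
        return UNKNOWN_STAGE
    return table.get((t, n, m), UNKNOWN_STAGE)


def validate_cohort_table(cohort: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise DataError(f"cohort table is missing columns {missing}")
    bad = set(cohort["stage"]) - set(STAGES) - {UNKNOWN_STAGE}
    if bad:
        raise DataError(f"cohort table contains unknown stages {sorted(bad)}")
    if (cohort[["tissue_area_cancer", "tissue_area_noncancer"]] < 0).any().any():
        raise DataError("tissue areas must be >= 0")
    return cohort


# ---------------------------------------------------------------------------
# area-weighted resampling
# ---------------------------------------------------------------------------

def area_weighted_resample(
    entropy_records: pd.DataFrame,
    cohort: pd.DataFrame,
    n_draws: int = 100_000,
    seed: int = 0,
    group_by: str | None = None,
    per_specimen_stratified: bool = False,
) -> pd.DataFrame:
    """Resample per-pixel entropies with inverse-area weights.

    Within each stratum — (channel, region_class), additionally split by
    stage when ``group_by='stage'`` — exactly ``n_draws`` pixels are drawn
    with replacement. Each pixel is weighted by the inverse of the area of
    its specimen's region of that class, so every specimen's region carries
    equal total weight. Specimens with stage ``"Unknown"`` are excluded from
    stage-stratified sets.

    ``per_specimen_stratified`` instead splits the draws equally across
    specimens first (uniform within each specimen's region); the two modes
    coincide in expectation.

    Returns a tidy frame with columns entropy, channel, region_class, stage,
    specimen_id.
    """
    if group_by not in (None, "stage"):
        raise ConfigError(f"group_by must be None or 'stage'; got {group_by!r}")
    validate_cohort_table(cohort)
    out_cols = ["entropy", "channel", "region_class", "stage", "specimen_id"]
    if n_draws == 0:
        return pd.DataFrame(columns=out_cols)
    if n_draws < 0:
        raise ConfigError(f"n_draws must be >= 0; got {n_draws}")

    records = entropy_records[
        entropy_records["region_label"].isin(REGION_CLASSES)
    ].copy()
    meta = cohort.set_index("specimen_id")
    unknown_ids = set(meta.index[meta["stage"] == UNKNOWN_STAGE])
    records["stage"] = records["specimen_id"].map(meta["stage"])
    if records["stage"].isna().any():
        orphans = sorted(
            set(records.loc[records["stage"].isna(), "specimen_id"])
        )
        raise DataError(f"entropy records reference unknown specimens {orphans}")
    if group_by == "stage":
        records = records[~records["specimen_id"].isin(unknown_ids)]

    area_col = {
        "cancer": "tissue_area_cancer",
        "noncancer": "tissue_area_noncancer",
    }

    rng = np.random.default_rng(seed)
    frames = []
    channels = sorted(records["channel"].unique())
    groups = [s for s in STAGES if (records["stage"] == s).any()] if group_by else [None]
    for channel in channels:
        for region in REGION_CLASSES:
            for group in groups:
                sel = (records["channel"] == channel) & (
                    records["region_label"] == region
                )
                if group is not None:
                    sel &= records["stage"] == group
                pool = records[sel]
                if pool.empty:
                    raise EmptyStratumError(
                        f"no pixels for stratum channel={channel}, "
                        f"region={region}"
                        + (f", stage={group}" if group is not None else "")
                    )
                areas = meta.loc[pool["specimen_id"], area_col[region]].to_numpy(
                    dtype=float
                )
                if (areas <= 0).any():
                    bad = sorted(set(pool["specimen_id"][areas <= 0]))
                    raise DataError(
                        f"non-positive {area_col[region]} for specimens {bad}"
                    )
                if per_specimen_stratified:
                    idx = _per_specimen_draws(pool, n_draws, rng)
                else:
                    w = 1.0 / areas
                    idx = rng.choice(
                        len(pool), size=n_draws, replace=True, p=w / w.sum()
                    )
                drawn = pool.iloc[idx]
                frames.append(
                    pd.DataFrame(
                        {
                            "entropy": drawn["entropy"].to_numpy(),
                            "channel": channel,
                            "region_class": region,
                            "stage": drawn["stage"].to_numpy(),
                            "specimen_id": drawn["specimen_id"].to_numpy(),
                        }
                    )
                )
    return pd.concat(frames, ignore_index=True)[out_cols]


def _per_specimen_draws(
    pool: pd.DataFrame, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    ids = sorted(pool["specimen_id"].unique())
    base, extra = divmod(n_draws, len(ids))
    chosen = []
    positions = {sid: np.flatnonzero(pool["specimen_id"].to_numpy() == sid) for sid in ids}
    for i, sid in enumerate(ids):
        take = base + (1 if i < extra else 0)
        chosen.append(rng.choice(positions[sid], size=take, replace=True))
    return np.concatenate(chosen)


# ---------------------------------------------------------------------------
# Welch's t-test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float


def welch_t_test(sample_a, sample_b) -> WelchResult:
    """Two-sided Welch's t-test (unequal variances, Welch–Satterthwaite df)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each sample needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return WelchResult(t=0.0, df=float(a.size + b.size - 2), p=1.0)
        raise InsufficientDataError("both samples have zero variance")
    sea, seb = va / a.size, vb / b.size
    t = (a.mean() - b.mean()) / math.sqrt(sea + seb)
    df = (sea + seb) ** 2 / (
        sea**2 / (a.size - 1) + seb**2 / (b.size - 1)
    )
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return WelchResult(t=float(t), df=float(df), p=p)


# ---------------------------------------------------------------------------
# histograms and Jensen-Shannon divergence
# ---------------------------------------------------------------------------

def default_bin_edges(bins: int = 64, max_entropy: float = 8.0) -> np.ndarray:
    """Equal-width bin edges over [0, max_entropy] bits."""
    if bins < 1:
        raise ConfigError(f"bins must be >= 1; got {bins}")
    return np.linspace(0.0, max_entropy, bins + 1)


def entropy_histogram(draws, bin_edges) -> np.ndarray:
    """Normalized histogram of entropy draws over the given edges.

    Values outside the edges are clipped into the end bins and counted (a
    warning is logged); the returned probabilities sum to 1.
    """
    values = np.asarray(draws, dtype=float)
    if values.size == 0:
        raise InsufficientDataError("cannot histogram an empty sample")
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or not (np.diff(edges) > 0).all():
        raise ConfigError("bin_edges must be a strictly increasing 1-D sequence")
    n_out = int(((values < edges[0]) | (values > edges[-1])).sum())
    if n_out:
        logger.warning("%d of %d draws outside bin range; clipped", n_out, values.size)
        values = np.clip(values, edges[0], edges[-1])
    counts, _ = np.histogram(values, bins=edges)
    return counts / counts.sum()


def jensen_shannon_divergence(P, Q) -> float:
    """JSD(P, Q) = KL(P||M)/2 + KL(Q||M)/2 with M = (P+Q)/2, in bits.

    Symmetric, bounded in [0, 1], zero iff P == Q.
    """
    p = np.asarray(P, dtype=float)
    q = np.asarray(Q, dtype=float)
    if p.shape != q.shape or p.ndim != 1:
        raise DataError(f"P and Q must be 1-D of equal length; got {p.shape}, {q.shape}")
    for name, vec in (("P", p), ("Q", q)):
        if (vec < 0).any():
            raise DataError(f"{name} has negative entries")
        if abs(vec.sum() - 1.0) > 1e-9:
            raise DataError(f"{name} sums to {vec.sum()!r}, not 1")
    m = (p + q) / 2.0
    def _kl(x: np.ndarray) -> float:
        nz = x > 0
        return float(np.sum(x[nz] * np.log2(x[nz] / m[nz])))
    return 0.5 * _kl(p) + 0.5 * _kl(q)


# ---------------------------------------------------------------------------
# comparison report
# ---------------------------------------------------------------------------

def compare_regions(
    resampled: pd.DataFrame,
    group_by: str | None = None,
    bin_edges=None,
) -> pd.DataFrame:
    """Cancer-vs-noncancer comparison per channel (and per stage if grouped).

    For each group x channel: Welch t-test (cancer minus noncancer), both
    normalized entropy histograms, and the JSD between them. Groups missing a
    region class are flagged in the ``note`` column; other groups are still
    reported.

    Returns columns: group, channel, n, mean_cancer, mean_noncancer, t, df,
    p, jsd, note.
    """
    if group_by not in (None, "stage"):
        raise ConfigError(f"group_by must be None or 'stage'; got {group_by!r}")
    if bin_edges is None:
        bin_edges = default_bin_edges()
    rows = []
    if group_by == "stage":
        groups = [s for s in STAGES if (resampled["stage"] == s).any()]
    else:
        groups = ["all"]
    for group in groups:
        sub = resampled if group == "all" else resampled[resampled["stage"] == group]
        for channel in sorted(sub["channel"].unique()):
            chan = sub[sub["channel"] == channel]
            cancer = chan.loc[chan["region_class"] == "cancer", "entropy"].to_numpy()
            noncancer = chan.loc[
                chan["region_class"] == "noncancer", "entropy"
            ].to_numpy()
            row = {
                "group": group,
                "channel": channel,
                "n": int(min(cancer.size, noncancer.size)),
                "mean_cancer": float(cancer.mean()) if cancer.size else math.nan,
                "mean_noncancer": float(noncancer.mean())
                if noncancer.size
                else math.nan,
                "t": math.nan,
                "df": math.nan,
                "p": math.nan,
                "jsd": math.nan,
                "note": "",
            }
            missing = [
                name
                for name, arr in (("cancer", cancer), ("noncancer", noncancer))
                if arr.size == 0
            ]
            if missing:
                row["note"] = f"missing region class: {', '.join(missing)}"
            else:
                welch = welch_t_test(cancer, noncancer)
                row.update(t=welch.t, df=welch.df, p=welch.p)
                hc = entropy_histogram(cancer, bin_edges)
                hn = entropy_histogram(noncancer, bin_edges)
                row["jsd"] = jensen_shannon_divergence(hn, hc)
            rows.append(row)
    return pd.DataFrame(rows)
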