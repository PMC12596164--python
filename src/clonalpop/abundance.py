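"""Statistics for detection-limit-censored Log10 CFU series.

Observations below the limit of detection (LOD) are left-censored: they are
carried with a censored flag and the LOD as numeric stand-in, never dropped.
Rank-based tests treat censored values as ties at the LOD, so any sub-LOD
value is exchangeable and results do not depend on the unobservable level.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CensoredSeries",
    "GroupTestResult",
    "OccupancySummary",
    "summarize",
    "kruskal_dunn",
    "occupancy_bimodality",
    "peak_lag",
]


@dataclass(frozen=True)
class CensoredSeries:
    """Replicated Log10 CFU observations over ordered time points.

    ``values[tp]`` and ``censored[tp]`` are parallel per-replicate lists;
    censored entries hold the LOD as their numeric stand-in.
    """

    compartment: str
    time_points: tuple[str, ...]
    values: dict[str, tuple[float, ...]]
    censored: dict[str, tuple[bool, ...]]
    lod: float = 1.0

    def __post_init__(self) -> None:
        if len(set(self.time_points)) != len(self.time_points):
            raise ValueError(f"{self.compartment}: duplicate time-point labels")
        for tp in self.time_points:
            vals = self.values.get(tp)
            flags = self.censored.get(tp)
            if not vals:
                raise ValueError(f"{self.compartment}: time point {tp!r} has no replicates")
            if flags is None or len(flags) != len(vals):
                raise ValueError(f"{self.compartment}: censored flags mismatch at {tp!r}")
            for v, c in zip(vals, flags):
                if c and abs(v - self.lod) > 1e-9:
                    raise ValueError(
                        f"{self.compartment}: censored replicate at {tp!r} must carry "
                        f"the LOD stand-in {self.lod}, got {v}"
                    )

    @classmethod
    def from_observations(
        cls,
        compartment: str,
        time_points: Sequence[str],
        raw_values: Mapping[str, Sequence[float]],
        lod: float = 1.0,
    ) -> "CensoredSeries":
        """Build a series from raw values, censoring everything below ``lod``."""
        values: dict[str, tuple[float, ...]] = {}
        censored: dict[str, tuple[bool, ...]] = {}
        for tp in time_points:
            vals = list(raw_values[tp])
            flags = [v < lod for v in vals]
            values[tp] = tuple(lod if c else float(v) for v, c in zip(vals, flags))
            censored[tp] = tuple(flags)
        return cls(compartment, tuple(time_points), values, censored, lod)

    def detected(self, tp: str) -> list[float]:
        return [v for v, c in zip(self.values[tp], self.censored[tp]) if not c]

    def substituted(self, tp: str) -> list[float]:
        """All replicates with censored entries at the LOD stand-in."""
        return list(self.values[tp])

    def all_censored(self) -> bool:
        return all(all(self.censored[tp]) for tp in self.time_points)

    def time_point_means(self) -> dict[str, float]:
        """Per-time-point mean of LOD-substituted replicates (peak detection)."""
        return {tp: float(np.mean(self.substituted(tp))) for tp in self.time_points}


@dataclass(frozen=True)
class GroupTestResult:
    """Kruskal-Wallis H with Dunn pairwise post-hoc, Bonferroni-adjusted."""

    groups: tuple[str, ...]
    kw_H: float
    kw_p: float
    dunn_z: dict[tuple[str, str], float]
    dunn_p_raw: dict[tuple[str, str], float]
    dunn_p_adjusted: dict[tuple[str, str], float]
    adjustment: str = "bonferroni"
    n_comparisons: int = 0


@dataclass(frozen=True)
class OccupancySummary:
    below_lod_fraction: float
    high_fraction: float
    intermediate_fraction: float
    bimodal: bool
    high_margin: float
    intermediate_threshold: float


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def summarize(series: CensoredSeries) -> pd.DataFrame:
    """Per-time-point n, detections, and mean/sd on the Log10 scale.

    ``mean``/``sd`` are over detected replicates (sample sd, ddof=1);
    ``mean_lod_sub``/``sd_lod_sub`` substitute the LOD for censored values.
    Time points with every replicate censored get the ``"<LOD"`` label.
    """
    rows = []
    for tp in series.time_points:
        det = series.detected(tp)
        sub = series.substituted(tp)
        n = len(sub)
        row = {
            "time_point": tp,
            "n": n,
            "n_detected": len(det),
            "mean": float(np.mean(det)) if det else math.nan,
            "sd": float(np.std(det, ddof=1)) if len(det) > 1 else math.nan,
            "mean_lod_sub": float(np.mean(sub)),
            "sd_lod_sub": float(np.std(sub, ddof=1)) if n > 1 else math.nan,
            "label": "<LOD" if not det else "",
        }
        rows.append(row)
    return pd.DataFrame(rows).set_index("time_point")


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn
# ---------------------------------------------------------------------------

def kruskal_dunn(groups: Mapping[str, Sequence[float]]) -> GroupTestResult:
    """Kruskal-Wallis over >=2 groups with Dunn's pairwise z post-hoc.

    Input values must already carry the LOD stand-in for censored
    observations (they then enter the ranks as ties at the LOD).  Dunn
    p-values are two-sided and Bonferroni-adjusted over all group pairs.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {}
    for g in labels:
        vals = np.asarray(list(groups[g]), dtype=float)
        if vals.size == 0:
            raise ValueError(f"group {g!r} has zero values")
        if vals.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
        arrays[g] = vals

    kw_H, kw_p = stats.kruskal(*[arrays[g] for g in labels])

    pooled = np.concatenate([arrays[g] for g in labels])
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    offsets = np.cumsum([0] + [arrays[g].size for g in labels])
    mean_ranks = {
        g: float(ranks[offsets[i] : offsets[i + 1]].mean()) for i, g in enumerate(labels)
    }

    # tie correction term of the Dunn variance: sum(t^3 - t) over tie groups
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(tie_counts.astype(float) ** 3 - tie_counts))

    pairs = list(itertools.combinations(labels, 2))
    k = len(pairs)
    dunn_z: dict[tuple[str, str], float] = {}
    dunn_p_raw: dict[tuple[str, str], float] = {}
    dunn_p_adj: dict[tuple[str, str], float] = {}
    var_base = n_total * (n_total + 1) / 12.0 - tie_sum / (12.0 * (n_total - 1))
    for a, b in pairs:
        se = math.sqrt(var_base * (1.0 / arrays[a].size + 1.0 / arrays[b].size))
        if se == 0.0:
            z = 0.0
        else:
            z = (mean_ranks[a] - mean_ranks[b]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        dunn_z[(a, b)] = float(z)
        dunn_p_raw[(a, b)] = float(p)
        dunn_p_adj[(a, b)] = float(min(1.0, p * k))

    return GroupTestResult(
        groups=tuple(labels),
        kw_H=float(kw_H),
        kw_p=float(kw_p),
        dunn_z=dunn_z,
        dunn_p_raw=dunn_p_raw,
        dunn_p_adjusted=dunn_p_adj,
        adjustment="bonferroni",
        n_comparisons=k,
    )


# ---------------------------------------------------------------------------
# occupancy / peaks
# ---------------------------------------------------------------------------

def occupancy_bimodality(
    series: CensoredSeries,
    high_margin: float = 1.0,
    intermediate_threshold: float = 0.2,
) -> OccupancySummary:
    """Classify time-point means as below-LOD / high / intermediate.

    A time point is below-LOD when every replicate is censored; high when
    its mean is within ``high_margin`` of the series maximum; intermediate
    otherwise.  The series is flagged bimodal when both extreme states
    occur and the intermediate fraction is at most the threshold.
    """
    if len(series.time_points) < 2:
        raise ValueError("need at least 2 time points")
    means = series.time_point_means()
    detected_states = []
    max_mean = max(means.values())
    for tp in series.time_points:
        if all(series.censored[tp]):
            detected_states.append("below")
        elif means[tp] >= max_mean - high_margin:
            detected_states.append("high")
        else:
            detected_states.append("intermediate")
    n = len(detected_states)
    below = detected_states.count("below") / n
    high = detected_states.count("high") / n
    inter = detected_states.count("intermediate") / n
    bimodal = below > 0 and high > 0 and inter <= intermediate_threshold
    return OccupancySummary(below, high, inter, bimodal, high_margin, intermediate_threshold)


def peak_lag(host: CensoredSeries, water: CensoredSeries) -> int:
    """Signed lag between the host and seawater abundance peaks.

    Computed over the time points the two series share, in host order, as
    index(water peak) - index(host peak) of the per-time-point means; ties
    break toward the earliest peak.  Positive lag means the host peaks
    first (host leads).
    """
    shared = [tp for tp in host.time_points if tp in set(water.time_points)]
    if len(shared) < 3:
        raise ValueError(
            f"series share only {len(shared)} time point(s); need at least 3"
        )
    for series, name in ((host, "host"), (water, "water")):
        if all(all(series.censored[tp]) for tp in shared):
            raise ValueError(f"{name} series is entirely censored on shared time points")
    host_means = host.time_point_means()
    water_means = water.time_point_means()
    host_peak = int(np.argmax([host_means[tp] for tp in shared]))
    water_peak = int(np.argmax([water_means[tp] for tp in shared]))
    return water_peak - host_peak


# ---------------------------------------------------------------------------
# CSV round-trip (schema shared with the simulator's writer)
# ---------------------------------------------------------------------------

ABUNDANCE_COLUMNS = ["compartment", "time_point", "replicate", "log10_cfu", "censored"]


def series_to_frame(series: CensoredSeries) -> pd.DataFrame:
    rows = []
    for tp in series.time_points:
        for i, (v, c) in enumerate(zip(series.values[tp], series.censored[tp]), start=1):
            rows.append(
                {
                    "compartment": series.compartment,
                    "time_point": tp,
                    "replicate": i,
                    "log10_cfu": v,
                    "censored": c,
                }
            )
    return pd.DataFrame(rows, columns=ABUNDANCE_COLUMNS)


def read_abundance_csv(path, lod: float = 1.0) -> dict[str, CensoredSeries]:
    """Read an abundance CSV into one CensoredSeries per compartment."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(ABUNDANCE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out: dict[str, CensoredSeries] = {}
    for comp, sub in df.groupby("compartment", sort=False):
        tps = list(dict.fromkeys(sub["time_point"].astype(str)))
        values: dict[str, tuple[float, ...]] = {}
        flags: dict[str, tuple[bool, ...]] = {}
        for tp in tps:
            block = sub[sub["time_point"].astype(str) == tp]
            cens = block["censored"].astype(bool).tolist()
            vals = [
                lod if c else float(v)
                for v, c in zip(block["log10_cfu"].tolist(), cens)
            ]
            values[tp] = tuple(vals)
            flags[tp] = tuple(cens)
        out[str(comp)] = CensoredSeries(str(comp), tuple(tps), values, flags, lod)
    if not out:
        raise ValueError(f"{path}: no abundance rows")
    return out
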