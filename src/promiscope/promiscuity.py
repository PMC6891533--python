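"""Promiscuity degrees, PD census and distribution summaries.

The promiscuity degree (PD) of a compound is the number of distinct targets
it is active against in its aggregated profile.  The census counts compounds
in exact-value bins (PD=0, PD=1) and nested threshold bins (PD>=2, >=5,
>=10, >=15); distribution summaries are boxplot-style five-number summaries
(min, q1, median, q3, max plus 1.5*IQR outliers) of tested-target counts per
PD bin and of calculated logP per promiscuity stratum.

Quartiles use linear interpolation between order statistics; the convention
is recorded in the summary metadata because conventions differ between
tools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from promiscope.filters import calc_logp
from promiscope.ingest import ActivityProfile, Molecule

log = logging.getLogger(__name__)

QUARTILE_METHOD = "linear"  # numpy interpolation method for percentiles


def promiscuity_degree(profile: ActivityProfile) -> int:
    """PD = number of targets the compound is active against."""
    return profile.pd


@dataclass(frozen=True)
class BinSpec:
    """One census bin: ``kind`` is "all", "eq" (PD == value) or
    "ge" (PD >= value)."""

    label: str
    kind: str
    value: int = 0

    def contains(self, pd: int) -> bool:
        if self.kind == "all":
            return True
        if self.kind == "eq":
            return pd == self.value
        if self.kind == "ge":
            return pd >= self.value
        raise ValueError(f"unknown bin kind {self.kind!r}")


DEFAULT_BINS: tuple[BinSpec, ...] = (
    BinSpec("all", "all"),
    BinSpec("PD=0", "eq", 0),
    BinSpec("PD=1", "eq", 1),
    BinSpec("PD>=2", "ge", 2),
    BinSpec("PD>=5", "ge", 5),
    BinSpec("PD>=10", "ge", 10),
    BinSpec("PD>=15", "ge", 15),
)


@dataclass
class PDCensus:
    """Counts of compounds per PD bin, with built-in consistency checks."""

    bins: tuple[BinSpec, ...]
    counts: dict[str, int]

    def __post_init__(self) -> None:
        labels = {b.label for b in self.bins}
        if set(self.counts) != labels:
            raise AssertionError("census counts do not cover the requested bins")
        self._check_consistency()

    def _check_consistency(self) -> None:
        c = self.counts
        # conservation over the exact/threshold partition, when present
        if {"all", "PD=0", "PD=1", "PD>=2"} <= set(c):
            if c["PD=0"] + c["PD=1"] + c["PD>=2"] != c["all"]:
                raise AssertionError(
                    "census conservation violated: PD=0 + PD=1 + PD>=2 != all"
                )
        # nesting of threshold bins
        ge_bins = sorted(
            (b for b in self.bins if b.kind == "ge"), key=lambda b: b.value
        )
        for lo, hi in zip(ge_bins, ge_bins[1:]):
            if c[lo.label] < c[hi.label]:
                raise AssertionError(
                    f"census nesting violated: {lo.label} < {hi.label}"
                )


def pd_census(
    profiles: Mapping[str, ActivityProfile] | Iterable[ActivityProfile],
    bins: Sequence[BinSpec] = DEFAULT_BINS,
) -> PDCensus:
    """Count compounds per PD bin."""
    plist = list(profiles.values()) if isinstance(profiles, Mapping) else list(profiles)
    pds = [p.pd for p in plist]
    counts = {b.label: sum(1 for pd in pds if b.contains(pd)) for b in bins}
    return PDCensus(bins=tuple(bins), counts=counts)


@dataclass
class DistributionSummary:
    """Boxplot-style five-number summary of one group of values."""

    group: str
    n: int
    min: float
    q1: float
    median: float
    q3: float
    max: float
    outliers: list[float] = field(default_factory=list)
    quartile_method: str = QUARTILE_METHOD

    def __post_init__(self) -> None:
        if self.n > 0 and not (
            self.min <= self.q1 <= self.median <= self.q3 <= self.max
        ):
            raise AssertionError(f"{self.group}: summary order violated")


def summarize(group: str, values: Iterable[float]) -> DistributionSummary:
    """Five-number summary with outliers beyond 1.5*IQR whiskers."""
    vals = np.asarray(sorted(values), dtype=float)
    if vals.size == 0:
        return DistributionSummary(group, 0, np.nan, np.nan, np.nan, np.nan, np.nan)
    q1, med, q3 = np.percentile(vals, [25, 50, 75], method=QUARTILE_METHOD)
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outliers = [float(v) for v in vals if v < lo_fence or v > hi_fence]
    return DistributionSummary(
        group=group,
        n=int(vals.size),
        min=float(vals[0]),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        max=float(vals[-1]),
        outliers=outliers,
    )


def tested_distribution_by_pd(
    profiles: Mapping[str, ActivityProfile],
    bins: Sequence[BinSpec] = DEFAULT_BINS,
) -> dict[str, DistributionSummary]:
    """Distribution of tested-target counts per PD bin (boxplot analog of
    per-bin test frequencies)."""
    out = {}
    for b in bins:
        vals = [p.n_tested for p in profiles.values() if b.contains(p.pd)]
        out[b.label] = summarize(b.label, vals)
    return out


def logp_distribution_by_pd(
    profiles: Mapping[str, ActivityProfile],
    molecules: Mapping[str, Molecule],
    strata: Sequence[BinSpec] = DEFAULT_BINS,
    with_density: bool = False,
) -> dict[str, DistributionSummary] | tuple[dict[str, DistributionSummary], dict]:
    """logP distribution per promiscuity stratum.

    Compounds without a resolvable structure are skipped (and logged).
    With ``with_density`` a Gaussian KDE curve (Scott's rule bandwidth) is
    additionally returned per stratum for plotting; the density is cosmetic.
    """
    logps: dict[str, float] = {}
    for cid in profiles:
        mol = molecules.get(cid)
        if mol is None:
            log.warning("logp_distribution_by_pd: no structure for %s; skipped", cid)
            continue
        logps[cid] = calc_logp(mol)

    summaries = {}
    densities = {}
    for b in strata:
        vals = [
            logps[cid]
            for cid, p in profiles.items()
            if cid in logps and b.contains(p.pd)
        ]
        summaries[b.label] = summarize(b.label, vals)
        if with_density and len(vals) > 2 and np.std(vals) > 0:
            from scipy.stats import gaussian_kde

            kde = gaussian_kde(vals, bw_method="scott")
            grid = np.linspace(min(vals) - 1, max(vals) + 1, 200)
            densities[b.label] = (grid, kde(grid))
    if with_density:
        return summaries, densities
    return summaries
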