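"""Percentage-based particle size distributions and USP <788> checks.

Static-imaging instruments cannot quantify absolute particle
concentration reliably, so size analysis is reported as percentages of
the counted population over half-open ECD bins [lo, hi).  The compendial
limits for injectables are checked on per-container counts: at most 6000
particles >= 10 um and at most 600 particles >= 25 um.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as _dc_fields

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .morphology import MorphologyRecord

USP_LIMIT_GE_10 = 6000
USP_LIMIT_GE_25 = 600


@dataclass
class SizeDistribution:
    """Counts and percentages over half-open [lo, hi) ECD bins."""

    bin_edges: tuple  # k+1 ascending edges (last may be inf)
    counts: np.ndarray  # length k
    n_total: int  # particles inside some bin
    n_excluded: int  # particles outside every bin

    @property
    def defined(self) -> bool:
        return self.n_total > 0

    @property
    def percents(self) -> np.ndarray | None:
        """Per-bin percentages summing to 100, or None for an empty set."""
        if not self.defined:
            return None
        return self.counts / self.n_total * 100.0

    def to_frame(self) -> pd.DataFrame:
        edges = self.bin_edges
        return pd.DataFrame(
            {
                "bin_lo": edges[:-1],
                "bin_hi": edges[1:],
                "count": self.counts,
                "percent": self.percents if self.defined else np.full(len(self.counts), np.nan),
            }
        )


def _ecds(records) -> np.ndarray:
    vals = np.asarray(
        [r.ecd if isinstance(r, MorphologyRecord) else float(r) for r in records], dtype=float
    )
    if np.any(vals <= 0):
        raise ValueError("ECDs must be positive")
    return vals


def bin_particles(records, bin_edges) -> SizeDistribution:
    """Assign each particle by ECD to exactly one half-open bin.

    Particles outside every bin are reported in ``n_excluded``.  An empty
    record list yields a flagged (``defined == False``) distribution, not
    silent NaNs.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be ascending with at least two values")
    records = list(records)
    k = len(edges) - 1
    if not records:
        return SizeDistribution(tuple(edges), np.zeros(k, dtype=int), 0, 0)
    ecds = _ecds(records)
    idx = np.searchsorted(edges, ecds, side="right") - 1
    inside = (idx >= 0) & (idx < k) & (ecds < edges[-1])
    counts = np.bincount(idx[inside], minlength=k).astype(int)
    return SizeDistribution(tuple(edges), counts, int(inside.sum()), int((~inside).sum()))


@dataclass
class UspCheck:
    """USP <788> particulate-limit verdict for one container."""

    count_ge_10: int
    count_ge_25: int
    pass_10: bool
    pass_25: bool

    @property
    def passes(self) -> bool:
        return self.pass_10 and self.pass_25


def usp_788_check(
    count_ge_10: int,
    count_ge_25: int,
    limit_10: int = USP_LIMIT_GE_10,
    limit_25: int = USP_LIMIT_GE_25,
) -> UspCheck:
    """'At or below' limits: the boundary counts pass."""
    if count_ge_10 < 0 or count_ge_25 < 0:
        raise ValueError("counts must be non-negative")
    return UspCheck(count_ge_10, count_ge_25, count_ge_10 <= limit_10, count_ge_25 <= limit_25)


_DESCRIPTORS = tuple(f.name for f in _dc_fields(MorphologyRecord) if f.name != "particle_id")


def binned_morphology_trend(records, bin_edges, descriptor: str) -> pd.DataFrame:
    """Per-size-bin mean/SD of one descriptor; empty bins get blank stats."""
    if descriptor not in _DESCRIPTORS:
        raise ValueError(f"unknown descriptor {descriptor!r}; have {_DESCRIPTORS}")
    edges = np.asarray(bin_edges, dtype=float)
    records = list(records)
    dist = bin_particles(records, edges)
    ecds = _ecds(records) if records else np.empty(0)
    idx = np.searchsorted(edges, ecds, side="right") - 1
    rows = []
    for b in range(len(edges) - 1):
        vals = np.asarray(
            [getattr(r, descriptor) for r, i, e in zip(records, idx, ecds) if i == b and e < edges[-1]]
        )
        rows.append(
            {
                "bin_lo": edges[b],
                "bin_hi": edges[b + 1],
                "n": len(vals),
                "mean": vals.mean() if len(vals) else np.nan,
                "sd": vals.std(ddof=1) if len(vals) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def compare_samples(dist_a: SizeDistribution, dist_b: SizeDistribution) -> np.ndarray:
    """Absolute per-bin percentage differences between two distributions."""
    if tuple(dist_a.bin_edges) != tuple(dist_b.bin_edges):
        raise ValueError("distributions have mismatched bin edges")
    if not (dist_a.defined and dist_b.defined):
        raise ValueError("cannot compare an empty distribution")
    return np.abs(dist_a.percents - dist_b.percents)


def welch_ttest(x, y) -> tuple[float, float]:
    """Welch's unequal-variance t-test (reporting plumbing only)."""
    res = _stats.ttest_ind(np.asarray(x, float), np.asarray(y, float), equal_var=False)
    return float(res.statistic), float(res.pvalue)


def plot_distribution(distributions: dict, path) -> None:
    """Grouped percentage bar chart, one group per bin (PNG/SVG by suffix)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    names = list(distributions)
    first = distributions[names[0]]
    k = len(first.counts)
    x = np.arange(k)
    width = 0.8 / max(len(names), 1)
    fig, ax = plt.subplots(figsize=(6, 4))
    for i, name in enumerate(names):
        d = distributions[name]
        pct = d.percents if d.defined else np.zeros(k)
        ax.bar(x + i * width, pct, width, label=name)
    labels = [
        f"[{lo:g}, {hi:g})" for lo, hi in zip(first.bin_edges[:-1], first.bin_edges[1:])
    ]
    ax.set_xticks(x + 0.4 - width / 2, labels)
    ax.set_ylabel("% of particles")
    ax.set_xlabel("ECD (um)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
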