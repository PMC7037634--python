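"""Age-binned, sex- and region-stratified trend analysis of per-sample G.

Samples are assigned to left-closed age bins (negative ages = prenatal,
0 = birth; the last bin is closed on the right), averaged per
(bin × region × sex) cell with standard errors, optionally averaged over
regions into per-sex curves, and the curves scanned for a female/male
crossover, late-life convergence, and trajectory extrema (peak and
post-peak trough).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AgeBinning:
    """Ordered age-bin edges (years) with one label per interval.

    Intervals are left-closed, right-open — ``[e_k, e_{k+1})`` — except the
    last, which is closed. The first edge may be negative (prenatal).
    """

    edges: tuple[float, ...]
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        edges = tuple(float(e) for e in self.edges)
        if len(edges) < 2:
            raise ValueError("need at least two bin edges")
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError(f"bin edges must be strictly increasing: {edges}")
        object.__setattr__(self, "edges", edges)
        if not self.labels:
            labels = tuple(
                f"{_fmt(a)}–{_fmt(b)}" for a, b in zip(edges, edges[1:])
            )
            object.__setattr__(self, "labels", labels)
        elif len(self.labels) != len(edges) - 1:
            raise ValueError("label count must equal interval count")

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    def bin_of(self, age: float) -> str | None:
        """Label of the bin containing ``age``, or None if out of range."""
        if age < self.edges[0] or age > self.edges[-1]:
            return None
        if age == self.edges[-1]:
            return self.labels[-1]
        idx = int(np.searchsorted(self.edges, age, side="right")) - 1
        return self.labels[idx]


def _fmt(x: float) -> str:
    return f"{x:g}"


#: Default reconstruction of the study's age brackets (years; negative =
#: prenatal). Brackets like 1–4 and 8–23 are taken from the named age ranges;
#: the 4–8 interval is kept as its own bin rather than left uncovered so the
#: binning partitions the full range.
DEFAULT_BINNING = AgeBinning(
    edges=(-0.75, -0.55, -0.3, 0.0, 1.0, 4.0, 8.0, 23.0, 27.0, 40.0, 55.0, 100.0)
)


def assign_age_bins(metadata: pd.DataFrame, binning: AgeBinning = DEFAULT_BINNING) -> pd.Series:
    """Map each sample to its age-bin label.

    Returns a Series indexed by sample_id, covering in-range samples only;
    out-of-range samples are logged and excluded.
    """
    ages = metadata.set_index("sample_id")["age_years"]
    assigned = ages.map(binning.bin_of)
    out_of_range = assigned.isna()
    if out_of_range.any():
        logger.info(
            "excluded %d samples with ages outside [%g, %g]: %s",
            int(out_of_range.sum()), binning.edges[0], binning.edges[-1],
            assigned.index[out_of_range].tolist(),
        )
    return assigned[~out_of_range].astype(str)


def summarize_bins(
    gibbs: pd.DataFrame,
    metadata: pd.DataFrame,
    binning: AgeBinning = DEFAULT_BINNING,
    group_by: Sequence[str] = ("region", "sex"),
) -> pd.DataFrame:
    """Mean ± standard error of total_G per (age bin × stratification cell).

    Parameters
    ----------
    gibbs:
        Per-sample table with columns ``sample_id`` and ``total_G``.
    metadata:
        Sample annotations (``sample_id, age_years, sex, region, ...``).
    group_by:
        Any subset of {"region", "sex", "hemisphere"}. Omitted keys appear
        in the output as ``"ALL"`` (region/hemisphere) or ``"pooled"`` (sex).

    Returns
    -------
    Tidy DataFrame with columns ``bin, region, sex, hemisphere (if grouped),
    mean_G, se_G, n``. ``se_G`` is the n−1 sample standard deviation divided
    by √n, missing (NaN) when n = 1. Empty cells are absent, not zero-filled.
    Samples with unknown sex are excluded whenever grouping by sex.
    """
    allowed = {"region", "sex", "hemisphere"}
    group_by = list(group_by)
    if not set(group_by) <= allowed:
        raise ValueError(f"group_by must be a subset of {allowed}")

    bins = assign_age_bins(metadata, binning).rename("bin")
    merged = gibbs.merge(metadata, on="sample_id").merge(
        bins, left_on="sample_id", right_index=True
    )
    if "sex" in group_by:
        known = merged["sex"].isin(["female", "male"])
        if (~known).any():
            logger.info("excluding %d unknown-sex samples from stratified summary",
                        int((~known).sum()))
        merged = merged[known]

    keys = ["bin"] + group_by
    rows = []
    for key_values, group in merged.groupby(keys, sort=False):
        if not isinstance(key_values, tuple):
            key_values = (key_values,)
        values = group["total_G"].to_numpy(dtype=float)
        n = len(values)
        row = {
            "bin": key_values[0],
            "region": "ALL",
            "sex": "pooled",
            "mean_G": float(values.mean()),
            "se_G": float(values.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
            "n": n,
        }
        row.update(dict(zip(group_by, key_values[1:])))
        rows.append(row)
    columns = ["bin", "region", "sex"] + (["hemisphere"] if "hemisphere" in group_by else [])
    out = pd.DataFrame(rows, columns=columns + ["mean_G", "se_G", "n"])
    order = {label: i for i, label in enumerate(binning.labels)}
    return out.sort_values(
        ["bin"] + columns[1:], key=lambda s: s.map(order) if s.name == "bin" else s
    ).reset_index(drop=True)


def average_over_regions(
    summaries: pd.DataFrame, weight: str = "regions"
) -> pd.DataFrame:
    """Collapse region-stratified bin summaries into per-sex curves.

    For each (bin, sex), takes the unweighted mean over the regions present
    in that bin (``weight="regions"``, the default: regions, not samples,
    are the averaging unit) or the sample-count-weighted mean
    (``weight="samples"``). Regions absent from a bin are simply excluded —
    no imputation. Returns columns ``bin, sex, mean_G, n_regions, n``.
    """
    if weight not in {"regions", "samples"}:
        raise ValueError("weight must be 'regions' or 'samples'")
    rows = []
    for (bin_label, sex), group in summaries.groupby(["bin", "sex"], sort=False):
        if weight == "regions":
            mean = float(group["mean_G"].mean())
        else:
            mean = float(np.average(group["mean_G"], weights=group["n"]))
        rows.append(
            {
                "bin": bin_label,
                "sex": sex,
                "mean_G": mean,
                "n_regions": int(group["region"].nunique()),
                "n": int(group["n"].sum()),
            }
        )
    return pd.DataFrame(rows, columns=["bin", "sex", "mean_G", "n_regions", "n"])


@dataclass
class CrossoverReport:
    """Sign structure of the female − male mean-G difference across bins."""

    crossovers: list[tuple[str, str]]
    converged: bool
    final_difference: float
    ties: list[str] = field(default_factory=list)


def detect_crossover(
    female: Mapping[str, float] | pd.Series,
    male: Mapping[str, float] | pd.Series,
    bin_order: Sequence[str],
    tolerance: float = 0.0,
) -> CrossoverReport:
    """Locate sign flips of (female − male) across consecutive shared bins.

    A crossover is reported between consecutive bins where the sign of the
    difference strictly flips; a zero difference is a tie, not a flip (ties
    are logged and returned). The convergence flag is set when the final
    shared bin's absolute difference is ≤ ``tolerance``. Bins missing from
    either curve are skipped. Raises ``ValueError`` with fewer than two
    shared bins.
    """
    female = pd.Series(dict(female), dtype=float)
    male = pd.Series(dict(male), dtype=float)
    shared = [b for b in bin_order if b in female.index and b in male.index]
    if len(shared) < 2:
        raise ValueError("need at least two shared bins to detect a crossover")
    diff = (female[shared] - male[shared]).to_numpy(dtype=float)
    signs = np.sign(diff)
    ties = [b for b, s in zip(shared, signs) if s == 0]
    if ties:
        logger.info("tied (zero-difference) bins: %s", ties)
    crossovers = [
        (shared[i], shared[i + 1])
        for i in range(len(shared) - 1)
        if signs[i] * signs[i + 1] < 0
    ]
    final_diff = float(diff[-1])
    return CrossoverReport(
        crossovers=crossovers,
        converged=bool(abs(final_diff) <= tolerance),
        final_difference=final_diff,
        ties=ties,
    )


@dataclass
class TrendExtrema:
    """Peak / post-peak-trough bins of one binned trajectory."""

    peak_bin: str
    trough_bin: str
    degenerate: bool


def trend_extrema(
    curve: Mapping[str, float] | pd.Series, bin_order: Sequence[str]
) -> TrendExtrema:
    """Global-maximum bin and the minimum bin among the bins after it.

    Ties break toward the earlier bin (logged). A curve whose maximum sits in
    the last bin has no post-peak bins; the trough is then reported as the
    peak bin itself with the ``degenerate`` flag set. Requires ≥ 3 bins.
    """
    series = pd.Series(dict(curve), dtype=float)
    ordered = [b for b in bin_order if b in series.index]
    if len(ordered) < 3:
        raise ValueError("trend extrema need at least three bins")
    values = series[ordered].to_numpy(dtype=float)
    peak_idx = int(np.argmax(values))  # argmax takes the first (earliest) tie
    degenerate = False
    if (values == values[peak_idx]).sum() > 1:
        logger.info("tied maximum; taking earliest bin %s", ordered[peak_idx])
        degenerate = True
    tail = values[peak_idx + 1 :]
    if tail.size == 0:
        trough_idx = peak_idx
        degenerate = True
    else:
        trough_idx = peak_idx + 1 + int(np.argmin(tail))
    return TrendExtrema(
        peak_bin=ordered[peak_idx], trough_bin=ordered[trough_idx], degenerate=degenerate
    )
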