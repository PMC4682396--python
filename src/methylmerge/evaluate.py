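"""Scoring of mapping and methylation detection.

Two families of metrics:

* Read-level, against the emulator's truth labels: mapping rate
  (mapped / total) and mapping accuracy (correctly placed / mapped).
* Methylation-level, against realized block truth: **d-accuracy** — per
  block, ``100·(1 − |true − detected|)`` where the detected block level is
  the unweighted mean of covered per-cytosine levels of the requested
  context inside the block — and **d-amount**, the number of cytosine
  positions detected at or above a depth threshold.

Paired one-sided Wilcoxon signed-rank tests compare per-block d-accuracy
vectors of two pipelines over the same blocks, and Pearson correlations
relate d-accuracy to mapping rate/accuracy across benchmark conditions.
All rates and accuracies are reported on the percent scale; methylation
levels stay on [0, 1].
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from methylmerge.errors import UsageError
from methylmerge.integrate import IntegratedCall
from methylmerge.io_calls import MapperCallSet, context_class
from methylmerge.simulate import BlockTruth, MappingOutcome, SimulatedRead


def mapping_rate(outcomes: Sequence[MappingOutcome]) -> float:
    """Mapped reads / total reads."""
    if not outcomes:
        raise UsageError("mapping rate undefined for zero reads")
    mapped = sum(1 for o in outcomes if o.status in ("correct", "incorrect"))
    return mapped / len(outcomes)


def mapping_accuracy(outcomes: Sequence[MappingOutcome]) -> float:
    """Correctly placed reads / mapped reads."""
    mapped = [o for o in outcomes if o.status in ("correct", "incorrect")]
    if not mapped:
        raise UsageError("mapping accuracy undefined with zero mapped reads")
    return sum(1 for o in mapped if o.status == "correct") / len(mapped)


def calls_to_level_frame(
    calls: Sequence[IntegratedCall] | MapperCallSet,
    method: str = "wave",
) -> pd.DataFrame:
    """Uniform per-position view: chrom, pos, context class, level, depth.

    Accepts either a single mapper's call set (level = n_meth/depth, zero
    depth dropped) or integrated calls (level of the chosen merging method,
    depth = summed per-mapper depth).
    """
    if isinstance(calls, MapperCallSet):
        rows = [
            (c.chrom, c.pos, context_class(c.context), c.n_meth / c.depth, c.depth)
            for c in calls
            if c.depth > 0
        ]
    else:
        rows = [
            (c.chrom, c.pos, context_class(c.context), c.level(method), c.depth_total)
            for c in calls
        ]
    return pd.DataFrame(rows, columns=["chrom", "pos", "context", "level", "depth"])


def block_detected_levels(
    calls: Sequence[IntegratedCall] | MapperCallSet,
    truth: Sequence[BlockTruth],
    context: str = "CG",
    method: str = "wave",
    min_depth: int = 1,
) -> pd.Series:
    """Detected methylation level of every block (NaN when no covered C).

    The block level is the unweighted mean over cytosines of the requested
    context class inside [start, end] whose depth passes ``min_depth``.
    """
    frame = calls_to_level_frame(calls, method=method)
    out = pd.Series(np.nan, index=[t.block_id for t in truth], dtype=float)
    if frame.empty:
        return out
    frame = frame[(frame["context"] == context) & (frame["depth"] >= min_depth)]
    if frame.empty:
        return out
    for t in truth:
        sel = frame[
            (frame["chrom"] == t.chrom)
            & (frame["pos"] >= t.start)
            & (frame["pos"] <= t.end)
        ]
        if len(sel):
            out[t.block_id] = sel["level"].mean()
    return out


def block_detected_level(
    calls, block: BlockTruth, context: str = "CG", method: str = "wave", min_depth: int = 1
) -> float:
    """Detected level of a single block (NaN when no covered C)."""
    return float(
        block_detected_levels(calls, [block], context=context, method=method, min_depth=min_depth)[
            block.block_id
        ]
    )


def d_accuracy(
    truth: Sequence[BlockTruth],
    detected_per_block: Mapping[int, float] | pd.Series,
    context: str = "CG",
) -> tuple[pd.Series, float]:
    """Per-block detection accuracy 100·(1 − |true − detected|) and its mean.

    Blocks whose detected level is undefined (no covered cytosine of the
    context), or whose realized truth is undefined, are excluded from both
    the vector and the mean; quantity is d-amount's job, not d-accuracy's.
    """
    det = pd.Series(detected_per_block, dtype=float)
    per_block = {}
    for t in truth:
        tv = t.true_mcg if context == "CG" else t.true_mch
        dv = det.get(t.block_id, np.nan)
        if np.isnan(tv) or np.isnan(dv):
            continue
        per_block[t.block_id] = 100.0 * (1.0 - abs(tv - dv))
    series = pd.Series(per_block, dtype=float)
    mean = float(series.mean()) if len(series) else float("nan")
    return series, mean


def d_amount(
    calls: Sequence[IntegratedCall] | MapperCallSet,
    min_depth: int = 1,
    context: str | None = None,
) -> int:
    """Number of cytosine positions detected at depth >= ``min_depth``.

    For integrated calls every emitted position already satisfied the
    covering-mapper rule; the depth filter applies to the summed depth.
    Optionally restricted to one context class (CG or CH).
    """
    if isinstance(calls, MapperCallSet):
        it: Iterable = ((c.depth, context_class(c.context)) for c in calls)
    else:
        it = ((c.depth_total, context_class(c.context)) for c in calls)
    return sum(
        1 for depth, ctx in it if depth >= min_depth and (context is None or ctx == context)
    )


def wilcoxon_paired(
    dacc_a: Sequence[float], dacc_b: Sequence[float], alternative: str = "greater"
) -> float:
    """One-sided Wilcoxon signed-rank p-value for paired per-block vectors.

    Tests H1: a > b (``alternative='greater'``).  Zero differences are
    dropped before ranking; if every pair ties, the statistic is undefined
    and p = 1.0 is returned with a warning.  The exact null distribution is
    used for up to 25 informative pairs, the normal approximation with
    continuity correction above.
    """
    a = np.asarray(dacc_a, dtype=float)
    b = np.asarray(dacc_b, dtype=float)
    if a.shape != b.shape:
        raise UsageError("paired vectors must have equal length")
    if a.size == 0:
        raise UsageError("need at least one pair")
    diffs = a - b
    nz = int(np.count_nonzero(diffs))
    if nz == 0:
        warnings.warn("all paired differences are zero; signed-rank test undefined, p=1.0")
        return 1.0
    method = "exact" if nz <= 25 else "approx"
    res = stats.wilcoxon(
        a, b, zero_method="wilcox", alternative=alternative, method=method, correction=True
    )
    return float(res.pvalue)


def correlate_metrics(reports: pd.DataFrame) -> dict[str, float]:
    """Pearson r of d-accuracy vs mapping rate and vs mapping accuracy.

    ``reports`` needs columns ``d_accuracy``, ``mapping_rate``,
    ``mapping_accuracy`` — one row per benchmark condition.
    """
    out = {}
    for col in ("mapping_rate", "mapping_accuracy"):
        x = reports[col].to_numpy(dtype=float)
        y = reports["d_accuracy"].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            raise UsageError(f"zero variance in {col!r} or d_accuracy; correlation undefined")
        out[col] = float(stats.pearsonr(x, y).statistic)
    return out


def t_density_summary(
    reads: Sequence[SimulatedRead], outcomes: Sequence[MappingOutcome]
) -> dict[str, float]:
    """Mean T fraction of reads, split by mapping outcome class.

    Returns {'correct': ..., 'incorrect': ..., 'unmapped': ...}; a class
    with no reads maps to NaN.
    """
    if len(reads) != len(outcomes):
        raise UsageError("reads and outcomes must align")
    acc: dict[str, list[float]] = {"correct": [], "incorrect": [], "unmapped": []}
    for r, o in zip(reads, outcomes):
        acc[o.status].append(r.t_fraction)
    return {k: (float(np.mean(v)) if v else float("nan")) for k, v in acc.items()}
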