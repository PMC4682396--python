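"""Consensus merging of per-cytosine methylation levels across mappers.

At cytosine position *i*, mapper *j* reports a methylation level

    M_ij = N^c_ij / (N^c_ij + N^t_ij)

from its counts of unconverted (C) and converted (T) reads.  Three merging
schemes combine the per-mapper levels of the mappers covering the position:

* ``Ave``   — the arithmetic mean of the M_ij,
* ``wAve``  — a depth-weighted mean, W_ij = N^d_ij / Σ_j N^d_ij, so mappers
  that placed more reads at the position carry more weight,
* ``pwAve`` — a Poisson-probability-weighted mean,
  W^p_ij = f(N^d_ij; λ_j) / Σ_j f(N^d_ij; λ_j), where f is the Poisson pmf
  and λ_j the mapper's genome-wide mean depth.  A depth that is typical for
  a mapper (near its λ) is trusted; an anomalously high local depth — the
  signature of reads piling up at a mismapping hotspot — is down-weighted.

A position is emitted only when at least ``min_mappers`` mappers cover it
with at least ``min_depth`` reads; uncovered mappers are excluded from all
sums and weight normalizations, so every merged level is a convex
combination of covering-mapper levels and stays within their range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import poisson

from methylmerge.errors import DataIntegrityError, UsageError
from methylmerge.io_calls import Key, MapperCallSet

logger = logging.getLogger(__name__)

METHODS = ("ave", "wave", "pwave")


def methylation_level(n_meth: int, n_unmeth: int) -> float:
    """Methylation level M = N^c / (N^c + N^t) at one cytosine.

    Undefined at zero depth; raises there.  (Inside integration a mapper
    with no reads at the position is simply excluded, so the textbook
    "level = 0 when uncovered" convention never contributes a term.)
    """
    if n_meth < 0 or n_unmeth < 0:
        raise DataIntegrityError(f"negative counts: n_meth={n_meth}, n_unmeth={n_unmeth}")
    depth = n_meth + n_unmeth
    if depth == 0:
        raise UsageError("methylation level undefined at zero depth")
    return n_meth / depth


def integrate_ave(levels: Sequence[float]) -> float:
    """Arithmetic mean of the covering mappers' levels (Ave)."""
    if len(levels) == 0:
        raise UsageError("need at least one covering mapper")
    return float(sum(levels) / len(levels))


def depth_weights(depths: Sequence[float]) -> np.ndarray:
    """Depth weights W_ij = N^d_ij / Σ_j N^d_ij over covering mappers."""
    d = np.asarray(depths, dtype=float)
    if d.size == 0:
        raise UsageError("need at least one covering mapper")
    if np.any(d <= 0):
        raise UsageError("depth weights require strictly positive depths")
    return d / d.sum()


def integrate_wave(levels: Sequence[float], depths: Sequence[float]) -> float:
    """Depth-weighted average wAve = Σ_j W_ij · M_ij."""
    m = np.asarray(levels, dtype=float)
    w = depth_weights(depths)
    if m.shape != w.shape:
        raise UsageError("levels and depths must align")
    return float(w @ m)


def poisson_weights(depths: Sequence[float], lambdas: Sequence[float]) -> np.ndarray:
    """Poisson weights W^p_ij = f(N^d_ij; λ_j) / Σ_j f(N^d_ij; λ_j).

    Evaluated in log space so extreme depth/λ combinations do not underflow;
    if every pmf is still zero (λ of 0 with positive depth for all mappers),
    falls back to plain depth weights with a logged warning.
    """
    d = np.asarray(depths, dtype=float)
    lam = np.asarray(lambdas, dtype=float)
    if d.size == 0:
        raise UsageError("need at least one covering mapper")
    if d.shape != lam.shape:
        raise UsageError("depths and lambdas must align")
    if np.any(lam < 0):
        raise UsageError("lambda must be >= 0")
    with np.errstate(divide="ignore"):
        logp = poisson.logpmf(np.round(d), lam)
    finite = np.isfinite(logp)
    if not finite.any():
        logger.warning(
            "all Poisson pmf values vanished (depths=%s, lambdas=%s); "
            "falling back to depth weights",
            d,
            lam,
        )
        return depth_weights(d)
    logp = np.where(finite, logp, -np.inf)
    logp -= logp[finite].max()
    w = np.exp(logp)
    return w / w.sum()


def integrate_pwave(
    levels: Sequence[float], depths: Sequence[float], lambdas: Sequence[float]
) -> float:
    """Poisson-weighted average pwAve = Σ_j W^p_ij · M_ij."""
    m = np.asarray(levels, dtype=float)
    w = poisson_weights(depths, lambdas)
    if m.shape != w.shape:
        raise UsageError("levels and depths must align")
    return float(w @ m)


@dataclass
class IntegratedCall:
    """Merged methylation call at one cytosine position.

    Carries the per-mapper inputs (levels, depths), the number of covering
    mappers n_i, the three merged levels, and the weight vectors actually
    used, so downstream reports can audit any position.
    """

    chrom: str
    pos: int
    strand: str
    context: str
    per_mapper_level: dict[str, float]
    per_mapper_depth: dict[str, int]
    n_covering: int
    level_ave: float = float("nan")
    level_wave: float = float("nan")
    level_pwave: float = float("nan")
    weights_wave: dict[str, float] = field(default_factory=dict)
    weights_pwave: dict[str, float] = field(default_factory=dict)

    @property
    def depth_total(self) -> int:
        return sum(self.per_mapper_depth.values())

    def level(self, method: str) -> float:
        return {"ave": self.level_ave, "wave": self.level_wave, "pwave": self.level_pwave}[method]


def integrate_positions(
    callsets: Sequence[MapperCallSet],
    method: Literal["ave", "wave", "pwave", "all"] = "all",
    min_mappers: int = 2,
    min_depth: int = 1,
    count_zero_level: bool = True,
) -> list[IntegratedCall]:
    """Merge call sets position by position.

    A mapper covers a position iff its depth there is >= ``min_depth``; a
    position is emitted iff the number of covering mappers n_i is >=
    ``min_mappers``.  Merged levels, and weight normalizations, run over the
    covering mappers only.

    ``count_zero_level=False`` switches n_i to the stricter reading "number
    of mappers reporting a level > 0", which additionally drops mappers that
    observed the position as fully unmethylated.  The default counts by
    coverage, so a confidently unmethylated call still participates.
    """
    if len(callsets) == 0:
        raise UsageError("need at least one call set to integrate")
    if method not in METHODS and method != "all":
        raise UsageError(f"method must be one of {METHODS + ('all',)}")
    if min_mappers < 1:
        raise UsageError("min_mappers must be >= 1")
    if min_depth < 1:
        raise UsageError("min_depth must be >= 1")
    ids = [cs.mapper_id for cs in callsets]
    if len(set(ids)) != len(ids):
        raise UsageError(f"mapper_ids must be unique, got {ids}")

    want_pwave = method in ("pwave", "all")
    keys: set[Key] = set()
    for cs in callsets:
        keys.update(cs.calls.keys())

    out: list[IntegratedCall] = []
    for key in sorted(keys):
        levels: dict[str, float] = {}
        depths: dict[str, int] = {}
        lams: dict[str, float] = {}
        context = None
        for cs in callsets:
            call = cs.calls.get(key)
            if call is None or call.depth < min_depth:
                continue
            level = call.n_meth / call.depth
            if not count_zero_level and level == 0.0:
                continue
            levels[cs.mapper_id] = level
            depths[cs.mapper_id] = call.depth
            lams[cs.mapper_id] = cs.lam
            context = call.context
        n_cov = len(levels)
        if n_cov < min_mappers or n_cov == 0:
            continue
        mids = list(levels)
        m = [levels[j] for j in mids]
        d = [depths[j] for j in mids]
        ic = IntegratedCall(
            chrom=key[0],
            pos=key[1],
            strand=key[2],
            context=context,  # type: ignore[arg-type]
            per_mapper_level=levels,
            per_mapper_depth=depths,
            n_covering=n_cov,
        )
        if method in ("ave", "all"):
            ic.level_ave = integrate_ave(m)
        if method in ("wave", "all"):
            w = depth_weights(d)
            ic.weights_wave = dict(zip(mids, w.tolist()))
            ic.level_wave = float(w @ np.asarray(m))
        if want_pwave:
            wp = poisson_weights(d, [lams[j] for j in mids])
            ic.weights_pwave = dict(zip(mids, wp.tolist()))
            ic.level_pwave = float(wp @ np.asarray(m))
        out.append(ic)
    logger.info(
        "integrated %d positions from %d mappers (min_mappers=%d, min_depth=%d)",
        len(out),
        len(callsets),
        min_mappers,
        min_depth,
    )
    return out


def integrated_to_frame(calls: Iterable[IntegratedCall]) -> pd.DataFrame:
    """Tabulate integrated calls (one row per position)."""
    rows = [
        {
            "chrom": c.chrom,
            "pos": c.pos,
            "strand": c.strand,
            "context": c.context,
            "n_covering": c.n_covering,
            "depth_total": c.depth_total,
            "level_ave": c.level_ave,
            "level_wave": c.level_wave,
            "level_pwave": c.level_pwave,
        }
        for c in calls
    ]
    cols = [
        "chrom",
        "pos",
        "strand",
        "context",
        "n_covering",
        "depth_total",
        "level_ave",
        "level_wave",
        "level_pwave",
    ]
    return pd.DataFrame(rows, columns=cols)


def write_integrated_tsv(calls: Sequence[IntegratedCall], path: str | Path) -> None:
    """Write integrated calls as a unified TSV with per-mapper depth columns."""
    mappers = sorted({j for c in calls for j in c.per_mapper_depth})
    with open(path, "w") as fh:
        fh.write("#format=methylmerge-integrated-v1\n")
        fh.write(f"#mappers={','.join(mappers)}\n")
        header = [
            "chrom",
            "pos",
            "strand",
            "context",
            "n_covering",
            "level_ave",
            "level_wave",
            "level_pwave",
        ] + [f"depth_{j}" for j in mappers]
        fh.write("#" + "\t".join(header) + "\n")
        for c in sorted(calls, key=lambda c: (c.chrom, c.pos, c.strand)):
            row = [
                c.chrom,
                str(c.pos),
                c.strand,
                c.context,
                str(c.n_covering),
                _fmt(c.level_ave),
                _fmt(c.level_wave),
                _fmt(c.level_pwave),
            ] + [str(c.per_mapper_depth.get(j, 0)) for j in mappers]
            fh.write("\t".join(row) + "\n")


def read_integrated_tsv(path: str | Path) -> list[IntegratedCall]:
    """Read a TSV written by :func:`write_integrated_tsv`.

    Per-mapper levels and weights are not serialized; reconstructed records
    carry per-mapper depths and the merged levels only.
    """
    calls: list[IntegratedCall] = []
    mappers: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#mappers="):
                raw = line[len("#mappers=") :].strip()
                mappers = raw.split(",") if raw else []
                continue
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            depths = {j: int(v) for j, v in zip(mappers, f[8:]) if int(v) > 0}
            calls.append(
                IntegratedCall(
                    chrom=f[0],
                    pos=int(f[1]),
                    strand=f[2],
                    context=f[3],
                    per_mapper_level={},
                    per_mapper_depth=depths,
                    n_covering=int(f[4]),
                    level_ave=_parse(f[5]),
                    level_wave=_parse(f[6]),
                    level_pwave=_parse(f[7]),
                )
            )
    return calls


def write_bedgraph(
    calls: Sequence[IntegratedCall], path: str | Path, method: str = "wave"
) -> None:
    """Export one merged level per position as bedGraph.

    The only place in the package where coordinates become 0-based
    half-open, on write.
    """
    if method not in METHODS:
        raise UsageError(f"method must be one of {METHODS}")
    with open(path, "w") as fh:
        for c in sorted(calls, key=lambda c: (c.chrom, c.pos)):
            fh.write(f"{c.chrom}\t{c.pos - 1}\t{c.pos}\t{c.level(method):.6g}\n")


def _fmt(x: float) -> str:
    return "NA" if x != x else f"{x:.10g}"


def _parse(s: str) -> float:
    return float("nan") if s == "NA" else float(s)
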