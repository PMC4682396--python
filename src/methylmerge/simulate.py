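"""Synthetic WGBS test bed: reference, bisulfite reads, mapper emulation.

The simulation replaces a real reference genome, a bisulfite read simulator
and the actual mapper binaries with a self-contained, seeded pipeline:

1. :func:`make_reference` builds a random reference partitioned into
   fixed-size blocks (500 bp by default); every block is assigned an
   independent uniform ground-truth methylation level for CpG and for CpH,
   and a chosen fraction of blocks carry near-identical copies of a shared
   motif to act as synthetic repeat elements.
2. :func:`generate_reads` draws reads uniformly within each block,
   bisulfite-converts unmethylated cytosines (each reference C is retained
   as C with probability equal to its block's truth level for its context,
   else read as T) and applies uniform substitution sequencing errors.
   The realized per-block conversion rates — what the reads actually carry,
   not the drawn targets — are recorded as the evaluation truth.
3. :func:`emulate_mapper` converts reads into per-cytosine call sets under a
   parametric :class:`MapperProfile`: reads are unmapped / mapped correctly /
   mapped to a wrong position with probabilities that respond to the read's
   realized error count, its T density, and repeat membership of its source
   block.  Mismapped reads deposit their C/T observations at the wrong
   location, producing the noise calls that consensus integration must
   correct.

All randomness flows through ``numpy.random.default_rng(seed)``; every
operation is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from methylmerge.errors import UsageError
from methylmerge.io_calls import CytosineCall, MapperCallSet

_A, _C, _G, _T = 0, 1, 2, 3
_CODE_TO_CHAR = np.frombuffer(b"ACGT", dtype=np.uint8)
_CHAR_TO_CODE = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CHAR_TO_CODE[_b] = _i
_CTX_NAMES = {1: "CG", 2: "CHG", 3: "CHH"}


@dataclass
class BlockTruth:
    """Ground-truth methylation of one reference block.

    ``true_mcg`` / ``true_mch`` are levels in [0, 1]: the drawn targets in
    the list returned by :func:`make_reference`, and the realized per-block
    conversion rates in the list returned by :func:`generate_reads` (the
    evaluation truth).  ``pooled_mcg``/``pooled_mch`` additionally record
    the read-pooled retention ratio of the realized lists.  Coordinates are
    1-based inclusive.
    """

    block_id: int
    chrom: str
    start: int
    end: int
    true_mcg: float
    true_mch: float
    is_repeat: bool = False
    pooled_mcg: float = float("nan")
    pooled_mch: float = float("nan")

    def __post_init__(self) -> None:
        for lv in (self.true_mcg, self.true_mch):
            if not (math.isnan(lv) or 0.0 <= lv <= 1.0):
                raise UsageError(f"methylation level {lv} outside [0,1]")
        if self.end < self.start:
            raise UsageError("block end < start")

    @property
    def size(self) -> int:
        return self.end - self.start + 1


@dataclass
class Reference:
    """A single-chromosome synthetic reference sequence."""

    chrom: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def codes(self) -> np.ndarray:
        """Base codes A=0 C=1 G=2 T=3 (cached)."""
        if not hasattr(self, "_codes"):
            self._codes = _CHAR_TO_CODE[
                np.frombuffer(self.sequence.encode("ascii"), dtype=np.uint8)
            ]
        return self._codes

    @property
    def context_codes(self) -> np.ndarray:
        """Per-position forward-strand context: 0 = not C, 1 = CG, 2 = CHG,
        3 = CHH (positions within two bases of the end fall back to CHH/CHG
        by padding with A)."""
        if not hasattr(self, "_ctx"):
            g = self.codes
            nxt1 = np.append(g[1:], _A)
            nxt2 = np.append(g[2:], [_A, _A])
            ctx = np.zeros(len(g), dtype=np.uint8)
            is_c = g == _C
            ctx[is_c] = 3  # CHH unless a G follows
            ctx[is_c & (nxt2 == _G)] = 2
            ctx[is_c & (nxt1 == _G)] = 1
            self._ctx = ctx
        return self._ctx


@dataclass
class SimulatedRead:
    """One simulated bisulfite read with its generation truth.

    ``c_offsets`` are the within-read offsets of reference cytosines covered
    by the read and ``c_methylated`` their retained/converted states (before
    sequencing errors).  ``error_mask`` marks bases hit by a substitution
    error.
    """

    read_id: str
    sequence: str
    true_chrom: str
    true_start: int  # 1-based
    true_strand: str
    block_id: int
    error_mask: np.ndarray
    c_offsets: np.ndarray
    c_methylated: np.ndarray

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def n_errors(self) -> int:
        return int(self.error_mask.sum())

    @property
    def t_fraction(self) -> float:
        return self.sequence.count("T") / len(self.sequence)


@dataclass(frozen=True)
class MapperProfile:
    """Parametric behavior of an emulated bisulfite-read mapper.

    The probability that a read maps at all is
    ``base_map_rate − error_sensitivity·(errors/length) −
    repeat_unmap_penalty·[repeat]``; conditional on mapping, the probability
    of landing at a wrong position is ``mismap_rate_base +
    error_mismap_sensitivity·(errors/length) +
    t_density_sensitivity·(T fraction) + repeat_mismap_penalty·[repeat]``.
    Both are clamped to [0, 1].
    """

    mapper_id: str
    base_map_rate: float
    error_sensitivity: float = 0.0
    mismap_rate_base: float = 0.0
    error_mismap_sensitivity: float = 0.0
    t_density_sensitivity: float = 0.0
    repeat_unmap_penalty: float = 0.0
    repeat_mismap_penalty: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.base_map_rate <= 1.0:
            raise UsageError("base_map_rate must be in [0,1]")
        if not 0.0 <= self.mismap_rate_base <= 1.0:
            raise UsageError("mismap_rate_base must be in [0,1]")
        for name in (
            "error_sensitivity",
            "error_mismap_sensitivity",
            "t_density_sensitivity",
            "repeat_unmap_penalty",
            "repeat_mismap_penalty",
        ):
            if getattr(self, name) < 0:
                raise UsageError(f"{name} must be >= 0")

    def map_probability(self, error_fraction, is_repeat) -> np.ndarray:
        p = (
            self.base_map_rate
            - self.error_sensitivity * np.asarray(error_fraction, dtype=float)
            - self.repeat_unmap_penalty * np.asarray(is_repeat, dtype=float)
        )
        return np.clip(p, 0.0, 1.0)

    def mismap_probability(self, t_fraction, is_repeat, error_fraction=0.0) -> np.ndarray:
        p = (
            self.mismap_rate_base
            + self.error_mismap_sensitivity * np.asarray(error_fraction, dtype=float)
            + self.t_density_sensitivity * np.asarray(t_fraction, dtype=float)
            + self.repeat_mismap_penalty * np.asarray(is_repeat, dtype=float)
        )
        return np.clip(p, 0.0, 1.0)


@dataclass(frozen=True)
class MappingOutcome:
    """Truth label for one read's emulated mapping."""

    read_id: str
    status: str  # unmapped | correct | incorrect
    block_id: int
    n_errors: int
    t_fraction: float
    is_repeat: bool


def _deplete_cpg(codes: np.ndarray, depletion: float, rng: np.random.Generator) -> None:
    """Disrupt a fraction of CG dinucleotides in place (mutate the C or the
    G to a random other base), emulating the CpG depletion of mammalian
    genomes, where the observed/expected CpG ratio is roughly 0.2-0.3."""
    if depletion <= 0:
        return
    cg = np.nonzero((codes[:-1] == _C) & (codes[1:] == _G))[0]
    hit = cg[rng.random(cg.size) < depletion]
    which = rng.integers(0, 2, size=hit.size)  # 0: mutate the C, 1: the G
    idx = hit + which
    codes[idx] = (codes[idx] + rng.integers(1, 4, size=idx.size)) % 4


def make_reference(
    n_blocks: int,
    block_size: int = 500,
    repeat_fraction: float = 0.0,
    seed: int | None = None,
    chrom: str = "chrS",
    repeat_divergence: float = 0.02,
    cpg_depletion: float = 0.75,
) -> tuple[Reference, list[BlockTruth]]:
    """Build a random reference with block-wise methylation truth.

    The backbone is i.i.d. uniform sequence with a ``cpg_depletion``
    fraction of CG dinucleotides disrupted afterwards, mimicking the CpG
    scarcity of mammalian chromosomes (roughly 6-8 forward-strand CpGs per
    500-bp block at the default, against ~31 for undepleted uniform
    sequence).  A ``repeat_fraction`` of blocks (rounded down, chosen at
    random) are near-identical copies of one shared, equally depleted motif
    — each copy diverges from it by ``repeat_divergence`` random
    substitutions — emulating an interspersed repeat family.  CpG and CpH
    truth levels are drawn independently and uniformly on [0, 1] per block.
    """
    if n_blocks < 1:
        raise UsageError("n_blocks must be >= 1")
    if not 0.0 <= repeat_fraction <= 1.0:
        raise UsageError("repeat_fraction must be in [0,1]")
    if not 0.0 <= cpg_depletion <= 1.0:
        raise UsageError("cpg_depletion must be in [0,1]")
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 4, size=n_blocks * block_size, dtype=np.uint8)
    _deplete_cpg(codes, cpg_depletion, rng)
    n_rep = int(n_blocks * repeat_fraction)
    rep_blocks = set(rng.choice(n_blocks, size=n_rep, replace=False).tolist()) if n_rep else set()
    if rep_blocks:
        motif = rng.integers(0, 4, size=block_size, dtype=np.uint8)
        _deplete_cpg(motif, cpg_depletion, rng)
        for b in sorted(rep_blocks):
            copy = motif.copy()
            mut = rng.random(block_size) < repeat_divergence
            copy[mut] = (copy[mut] + rng.integers(1, 4, size=int(mut.sum()))) % 4
            codes[b * block_size : (b + 1) * block_size] = copy
    mcg = rng.uniform(0.0, 1.0, size=n_blocks)
    mch = rng.uniform(0.0, 1.0, size=n_blocks)
    truth = [
        BlockTruth(
            block_id=b,
            chrom=chrom,
            start=b * block_size + 1,
            end=(b + 1) * block_size,
            true_mcg=float(mcg[b]),
            true_mch=float(mch[b]),
            is_repeat=b in rep_blocks,
        )
        for b in range(n_blocks)
    ]
    seq = _CODE_TO_CHAR[codes].tobytes().decode("ascii")
    return Reference(chrom=chrom, sequence=seq), truth


def generate_reads(
    truth: Sequence[BlockTruth],
    reference: Reference,
    read_length: int,
    reads_per_block: int,
    error_rate: float,
    seed: int | None = None,
) -> tuple[list[SimulatedRead], list[BlockTruth]]:
    """Simulate bisulfite reads and record the realized block truth.

    Reads start uniformly within their block and never straddle block
    boundaries.  Each reference C in a read is retained with probability
    equal to its block's truth level for its context (CG vs CH), otherwise
    read as T; substitution errors then hit each base independently at
    ``error_rate``, replacing it by a uniformly chosen different base.

    Returns the reads and a realized-truth list: per block and context, the
    unweighted mean over covered cytosine positions of the per-position
    retention fraction (NaN for a context with no covered C).  This —
    not the drawn target — is the level the read set actually encodes, and
    is what detection accuracy is scored against.  The read-pooled retention
    ratio is kept alongside in ``pooled_mcg``/``pooled_mch``.
    """
    if not truth:
        raise UsageError("need at least one block")
    block_size = truth[0].size
    if read_length > block_size:
        raise UsageError(f"read_length {read_length} > block_size {block_size}")
    if not 0.0 <= error_rate <= 1.0:
        raise UsageError("error_rate must be in [0,1]")
    if reads_per_block < 1:
        raise UsageError("reads_per_block must be >= 1")

    rng = np.random.default_rng(seed)
    g = reference.codes
    ctx = reference.context_codes
    n_blocks = len(truth)
    n_reads = n_blocks * reads_per_block
    L = read_length

    block_idx = np.repeat(np.arange(n_blocks), reads_per_block)
    block_start0 = np.array([t.start - 1 for t in truth])
    starts0 = block_start0[block_idx] + rng.integers(
        0, block_size - L + 1, size=n_reads
    )
    pos2d = starts0[:, None] + np.arange(L)[None, :]
    base2d = g[pos2d].copy()
    ctx2d = ctx[pos2d]
    cmask = base2d == _C

    mcg = np.array([t.true_mcg for t in truth])
    mch = np.array([t.true_mch for t in truth])
    p_keep = np.where(ctx2d == 1, mcg[block_idx][:, None], mch[block_idx][:, None])
    retained = cmask & (rng.random((n_reads, L)) < p_keep)
    base2d[cmask & ~retained] = _T

    # realized truth tallied before sequencing errors
    G = len(g)
    tot_c = np.bincount(pos2d[cmask], minlength=G)
    meth_c = np.bincount(pos2d[retained], minlength=G)

    err2d = rng.random((n_reads, L)) < error_rate
    if err2d.any():
        shift = rng.integers(1, 4, size=int(err2d.sum()), dtype=np.uint8)
        base2d[err2d] = (base2d[err2d] + shift) % 4

    reads = _materialize_reads(
        reference, base2d, starts0, block_idx, err2d, cmask, retained
    )
    realized = _realized_truth(truth, ctx, tot_c, meth_c)
    return reads, realized


def _materialize_reads(reference, base2d, starts0, block_idx, err2d, cmask, retained):
    n_reads, L = base2d.shape
    allbytes = _CODE_TO_CHAR[base2d].tobytes()
    reads = []
    for i in range(n_reads):
        offs = np.nonzero(cmask[i])[0]
        reads.append(
            SimulatedRead(
                read_id=f"r{i:07d}",
                sequence=allbytes[i * L : (i + 1) * L].decode("ascii"),
                true_chrom=reference.chrom,
                true_start=int(starts0[i]) + 1,
                true_strand="+",
                block_id=int(block_idx[i]),
                error_mask=err2d[i].copy(),
                c_offsets=offs,
                c_methylated=retained[i, offs].copy(),
            )
        )
    return reads


def _realized_truth(truth, ctx, tot_c, meth_c):
    block_size = truth[0].size
    covered = tot_c > 0
    realized = []
    for t in truth:
        sl = slice(t.start - 1, t.end)
        vals = {}
        pooled = {}
        for name, want in (("cg", 1), ("ch", (2, 3))):
            if isinstance(want, tuple):
                sel = covered[sl] & ((ctx[sl] == want[0]) | (ctx[sl] == want[1]))
            else:
                sel = covered[sl] & (ctx[sl] == want)
            if sel.any():
                ratios = meth_c[sl][sel] / tot_c[sl][sel]
                vals[name] = float(np.mean(ratios))
                pooled[name] = float(meth_c[sl][sel].sum() / tot_c[sl][sel].sum())
            else:
                vals[name] = float("nan")
                pooled[name] = float("nan")
        realized.append(
            replace(
                t,
                true_mcg=vals["cg"],
                true_mch=vals["ch"],
                pooled_mcg=pooled["cg"],
                pooled_mch=pooled["ch"],
            )
        )
    return realized


def emulate_mapper(
    reads: Sequence[SimulatedRead],
    truth: Sequence[BlockTruth],
    reference: Reference,
    profile: MapperProfile,
    seed: int | None = None,
) -> tuple[MapperCallSet, list[MappingOutcome]]:
    """Turn simulated reads into one mapper's per-cytosine call set.

    Each read is independently unmapped, mapped correctly, or mapped to a
    uniformly chosen wrong position, with probabilities given by the
    profile evaluated on the read's realized error fraction, T density and
    repeat membership.  Mapped reads (correct and incorrect alike) deposit
    their base observations on the reference: at every forward-strand
    reference C under the alignment, an observed C counts as methylated, an
    observed T as unmethylated, and any other base is ignored.  The call
    set's λ is the total deposited depth divided by the number of reference
    cytosines (mean depth over the whole reference).
    """
    if not reads:
        raise UsageError("need at least one read")
    L = len(reads[0])
    if any(len(r) != L for r in reads):
        raise UsageError("emulate_mapper requires equal-length reads")
    rng = np.random.default_rng(seed)
    n = len(reads)
    g = reference.codes
    ctx = reference.context_codes
    G = len(g)

    codes = _CHAR_TO_CODE[
        np.frombuffer("".join(r.sequence for r in reads).encode("ascii"), dtype=np.uint8)
    ].reshape(n, L)
    n_err = np.array([int(r.error_mask.sum()) for r in reads])
    t_frac = (codes == _T).mean(axis=1)
    is_rep = np.array([truth[r.block_id].is_repeat for r in reads])
    starts0 = np.array([r.true_start - 1 for r in reads])

    p_map = profile.map_probability(n_err / L, is_rep)
    mapped = rng.random(n) < p_map
    p_mis = profile.mismap_probability(t_frac, is_rep, n_err / L)
    mis = mapped & (rng.random(n) < p_mis)
    correct = mapped & ~mis

    aligned0 = starts0.copy()
    n_mis = int(mis.sum())
    if n_mis:
        aligned0[mis] = rng.integers(0, G - L + 1, size=n_mis)

    meth = np.zeros(G, dtype=np.int64)
    unmeth = np.zeros(G, dtype=np.int64)
    midx = np.nonzero(mapped)[0]
    if midx.size:
        pos2d = aligned0[midx][:, None] + np.arange(L)[None, :]
        is_ref_c = (g == _C)[pos2d]
        obs = codes[midx]
        meth += np.bincount(pos2d[is_ref_c & (obs == _C)], minlength=G)
        unmeth += np.bincount(pos2d[is_ref_c & (obs == _T)], minlength=G)

    callset = MapperCallSet(mapper_id=profile.mapper_id, meta="emulated")
    depth = meth + unmeth
    for p0 in np.nonzero(depth)[0]:
        callset.add(
            CytosineCall(
                chrom=reference.chrom,
                pos=int(p0) + 1,
                strand="+",
                context=_CTX_NAMES[int(ctx[p0])],
                n_meth=int(meth[p0]),
                n_unmeth=int(unmeth[p0]),
            )
        )
    n_ref_c = int((g == _C).sum())
    callset.lam = float(depth.sum() / n_ref_c) if n_ref_c else 0.0

    status = np.where(correct, "correct", np.where(mis, "incorrect", "unmapped"))
    outcomes = [
        MappingOutcome(
            read_id=reads[i].read_id,
            status=str(status[i]),
            block_id=reads[i].block_id,
            n_errors=int(n_err[i]),
            t_fraction=float(t_frac[i]),
            is_repeat=bool(is_rep[i]),
        )
        for i in range(n)
    ]
    return callset, outcomes


def preset_profiles() -> dict[str, MapperProfile]:
    """Three presets reproducing the characteristic behaviors of the
    popular bisulfite mappers at mean depth 10.

    * ``bismark-like`` — three-letter aligner: very accurate on clean reads
      and insensitive to read T density, but loses both mapping rate and
      accuracy as read error grows, and tends to leave repeat-derived reads
      unmapped.
    * ``bsmap-like`` — wild-card aligner: the highest mapping rate on clean
      reads but the lowest accuracy; both collapse at high error (its rate
      dropping below bismark-like's), and T-rich (hypomethylated) and
      repeat-derived reads are preferentially mismapped.
    * ``bsseeker2-like`` — three-letter aligner whose rate and accuracy
      barely respond to read error, but which shares the T-density
      mismapping bias and leaves repeat reads unmapped.
    """
    return {
        "bismark-like": MapperProfile(
            mapper_id="bismark-like",
            base_map_rate=0.96,
            error_sensitivity=8.0,
            mismap_rate_base=0.001,
            error_mismap_sensitivity=0.2,
            t_density_sensitivity=0.0,
            repeat_unmap_penalty=0.30,
            repeat_mismap_penalty=0.0,
        ),
        "bsmap-like": MapperProfile(
            mapper_id="bsmap-like",
            base_map_rate=0.99,
            error_sensitivity=8.5,
            mismap_rate_base=0.015,
            error_mismap_sensitivity=0.15,
            t_density_sensitivity=0.12,
            repeat_unmap_penalty=0.0,
            repeat_mismap_penalty=0.25,
        ),
        "bsseeker2-like": MapperProfile(
            mapper_id="bsseeker2-like",
            base_map_rate=0.90,
            error_sensitivity=0.5,
            mismap_rate_base=0.025,
            error_mismap_sensitivity=0.0,
            t_density_sensitivity=0.10,
            repeat_unmap_penalty=0.20,
            repeat_mismap_penalty=0.0,
        ),
    }


def write_fasta(reference: Reference, path: str | Path, width: int = 60) -> None:
    """Write the synthetic reference as FASTA."""
    with open(path, "w") as fh:
        fh.write(f">{reference.chrom}\n")
        for i in range(0, len(reference.sequence), width):
            fh.write(reference.sequence[i : i + width] + "\n")


def write_truth_tsv(truth: Sequence[BlockTruth], path: str | Path) -> None:
    """Write block truth as TSV (levels NaN-safe, '#'-prefixed header)."""
    with open(path, "w") as fh:
        fh.write("#format=methylmerge-truth-v1\n")
        fh.write(
            "#block_id\tchrom\tstart\tend\ttrue_mcg\ttrue_mch"
            "\tpooled_mcg\tpooled_mch\tis_repeat\n"
        )
        for t in truth:
            fh.write(
                f"{t.block_id}\t{t.chrom}\t{t.start}\t{t.end}"
                f"\t{_fmtf(t.true_mcg)}\t{_fmtf(t.true_mch)}"
                f"\t{_fmtf(t.pooled_mcg)}\t{_fmtf(t.pooled_mch)}"
                f"\t{int(t.is_repeat)}\n"
            )


def read_truth_tsv(path: str | Path) -> list[BlockTruth]:
    """Read a TSV written by :func:`write_truth_tsv`."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            out.append(
                BlockTruth(
                    block_id=int(f[0]),
                    chrom=f[1],
                    start=int(f[2]),
                    end=int(f[3]),
                    true_mcg=_parsef(f[4]),
                    true_mch=_parsef(f[5]),
                    pooled_mcg=_parsef(f[6]),
                    pooled_mch=_parsef(f[7]),
                    is_repeat=bool(int(f[8])),
                )
            )
    return out


def write_outcomes_tsv(outcomes: Sequence[MappingOutcome], path: str | Path) -> None:
    """Write per-read mapping outcomes as TSV."""
    with open(path, "w") as fh:
        fh.write("#read_id\tstatus\tblock_id\tn_errors\tt_fraction\tis_repeat\n")
        for o in outcomes:
            fh.write(
                f"{o.read_id}\t{o.status}\t{o.block_id}\t{o.n_errors}"
                f"\t{o.t_fraction:.6g}\t{int(o.is_repeat)}\n"
            )


def read_outcomes_tsv(path: str | Path) -> list[MappingOutcome]:
    """Read a TSV written by :func:`write_outcomes_tsv`."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            out.append(
                MappingOutcome(
                    read_id=f[0],
                    status=f[1],
                    block_id=int(f[2]),
                    n_errors=int(f[3]),
                    t_fraction=float(f[4]),
                    is_repeat=bool(int(f[5])),
                )
            )
    return out


def _fmtf(x: float) -> str:
    return "NA" if x != x else f"{x:.10g}"


def _parsef(s: str) -> float:
    return float("nan") if s == "NA" else float(s)


def write_fastq(reads: Sequence[SimulatedRead], path: str | Path) -> None:
    """Write simulated reads as FASTQ with the origin encoded in the name
    (``id|chrom:start:strand``) and constant quality, for use with real
    mappers outside the test suite."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(
                f"@{r.read_id}|{r.true_chrom}:{r.true_start}:{r.true_strand}\n"
                f"{r.sequence}\n+\n{'I' * len(r)}\n"
            )
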