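"""Readers and writers for per-cytosine methylation call files.

Supported dialects
------------------
* CGmap (BS-seeker2): ``chrom  nuc  pos  context  dinuc  level  n_meth  depth``
* Bismark genome-wide cytosine report:
  ``chrom  pos  strand  n_meth  n_unmeth  context  trinucleotide``
* Bismark coverage (``.cov``): ``chrom  start  end  percent  n_meth  n_unmeth``
* BSMAP ``methratio.py`` TSV:
  ``chrom  pos  strand  context  ratio  eff_CT  C_count  CT_count  ...``
* The package's own unified TSV (lossless round trip, ``#``-prefixed header).

All coordinates are 1-based and strand-specific throughout the package; the
strand a cytosine sits on is the strand of its call, and no 0-based
conversion happens internally (bedGraph export converts on write only).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from methylmerge.errors import CallFormatError, DataIntegrityError, UsageError

CONTEXTS = ("CG", "CHG", "CHH")

UNIFIED_FORMAT = "methylmerge-calls-v1"

Key = tuple[str, int, str]


def context_class(context: str) -> str:
    """Collapse a trinucleotide context to the two-class scheme: CG or CH.

    CH is the union of CHG and CHH (H = A, C or T).
    """
    if context == "CG":
        return "CG"
    if context in ("CHG", "CHH", "CH"):
        return "CH"
    raise ValueError(f"unknown cytosine context {context!r}")


@dataclass(frozen=True)
class CytosineCall:
    """One mapper's read counts at a single cytosine.

    ``pos`` is the 1-based position of the cytosine on its strand; ``n_meth``
    counts reads observing an unconverted C, ``n_unmeth`` reads observing a
    bisulfite-converted T.  Total depth is ``n_meth + n_unmeth``.
    """

    chrom: str
    pos: int
    strand: str
    context: str
    n_meth: int
    n_unmeth: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise DataIntegrityError(f"position must be >= 1, got {self.pos}")
        if self.strand not in ("+", "-"):
            raise DataIntegrityError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.context not in CONTEXTS:
            raise DataIntegrityError(f"context must be one of {CONTEXTS}, got {self.context!r}")
        if self.n_meth < 0 or self.n_unmeth < 0:
            raise DataIntegrityError(
                f"negative counts at {self.chrom}:{self.pos}: "
                f"n_meth={self.n_meth}, n_unmeth={self.n_unmeth}"
            )

    @property
    def depth(self) -> int:
        return self.n_meth + self.n_unmeth

    @property
    def key(self) -> Key:
        return (self.chrom, self.pos, self.strand)


@dataclass
class MapperCallSet:
    """All calls of one mapper plus its genome-wide mean depth lambda.

    ``calls`` maps (chrom, pos, strand) to a CytosineCall; a position absent
    from the mapping is uncovered by this mapper (never a zero-depth record).
    ``lam`` is the mapper's mean read depth over the reference cytosines, the
    Poisson parameter used for probabilistic weighting.
    """

    mapper_id: str
    calls: dict[Key, CytosineCall] = field(default_factory=dict)
    lam: float = 0.0
    meta: str = ""

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise DataIntegrityError(f"lambda must be >= 0, got {self.lam}")

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self) -> Iterator[CytosineCall]:
        return iter(self.calls.values())

    def add(self, call: CytosineCall) -> None:
        if call.key in self.calls:
            raise DataIntegrityError(
                f"duplicate call at {call.chrom}:{call.pos}:{call.strand} "
                f"in mapper {self.mapper_id!r}"
            )
        self.calls[call.key] = call


def _split(line: str, path: str, lineno: int, min_fields: int) -> list[str]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) == 1:  # tolerate space-separated variants
        fields = line.split()
    if len(fields) < min_fields:
        raise CallFormatError(
            f"expected >= {min_fields} tab-separated fields, got {len(fields)}",
            path=path,
            line=lineno,
        )
    return fields


def _to_int(text: str, what: str, path: str, lineno: int) -> int:
    try:
        return int(text)
    except ValueError:
        raise CallFormatError(f"non-integer {what} {text!r}", path=path, line=lineno) from None


def read_cgmap(path: str | Path, mapper_id: str = "bsseeker2") -> MapperCallSet:
    """Read a BS-seeker2 CGmap file.

    Strand is inferred from the nucleotide column (C = forward strand,
    G = reverse strand); depth is the total-count column and the
    unmethylated count is depth minus the methylated count.
    """
    path = Path(path)
    cs = MapperCallSet(mapper_id=mapper_id, meta="cgmap")
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            f = _split(line, str(path), lineno, 8)
            chrom, nuc, pos_s, context = f[0], f[1], f[2], f[3]
            n_meth = _to_int(f[6], "methylated count", str(path), lineno)
            depth = _to_int(f[7], "total count", str(path), lineno)
            if nuc not in ("C", "G"):
                raise CallFormatError(
                    f"nucleotide column must be C or G, got {nuc!r}", str(path), lineno
                )
            if depth < n_meth:
                raise DataIntegrityError(
                    f"total count {depth} < methylated count {n_meth} "
                    f"at {path}:{lineno}"
                )
            cs.add(
                CytosineCall(
                    chrom=chrom,
                    pos=_to_int(pos_s, "position", str(path), lineno),
                    strand="+" if nuc == "C" else "-",
                    context=_normalize_context(context, str(path), lineno),
                    n_meth=n_meth,
                    n_unmeth=depth - n_meth,
                )
            )
    return cs


def read_bismark_report(path: str | Path, mapper_id: str = "bismark") -> MapperCallSet:
    """Read a Bismark genome-wide cytosine report (CX report)."""
    path = Path(path)
    cs = MapperCallSet(mapper_id=mapper_id, meta="bismark-report")
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            f = _split(line, str(path), lineno, 6)
            chrom, pos_s, strand = f[0], f[1], f[2]
            if strand not in ("+", "-"):
                raise CallFormatError(f"bad strand {strand!r}", str(path), lineno)
            cs.add(
                CytosineCall(
                    chrom=chrom,
                    pos=_to_int(pos_s, "position", str(path), lineno),
                    strand=strand,
                    context=_normalize_context(f[5], str(path), lineno),
                    n_meth=_to_int(f[3], "methylated count", str(path), lineno),
                    n_unmeth=_to_int(f[4], "unmethylated count", str(path), lineno),
                )
            )
    return cs


def read_bismark_cov(path: str | Path, mapper_id: str = "bismark") -> MapperCallSet:
    """Read a Bismark coverage (``.cov``) file.

    The coverage format carries neither strand nor context; Bismark emits it
    for CpG calls on the forward-reported coordinate, so calls are recorded
    as forward-strand CG.  Prefer the cytosine report when CH contexts or
    strand matter.
    """
    path = Path(path)
    cs = MapperCallSet(mapper_id=mapper_id, meta="bismark-cov")
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            f = _split(line, str(path), lineno, 6)
            start = _to_int(f[1], "start", str(path), lineno)
            end = _to_int(f[2], "end", str(path), lineno)
            if end < start:
                raise CallFormatError(f"end {end} < start {start}", str(path), lineno)
            cs.add(
                CytosineCall(
                    chrom=f[0],
                    pos=start,
                    strand="+",
                    context="CG",
                    n_meth=_to_int(f[4], "methylated count", str(path), lineno),
                    n_unmeth=_to_int(f[5], "unmethylated count", str(path), lineno),
                )
            )
    return cs


def read_methratio(path: str | Path, mapper_id: str = "bsmap") -> MapperCallSet:
    """Read a BSMAP ``methratio.py`` TSV.

    Depth is the integer CT_count column; the fractional eff_CT_count column
    (effective coverage after mismatch filtering) is deliberately ignored so
    that counts stay integral.  A header line starting with ``chr`` is
    skipped.
    """
    path = Path(path)
    cs = MapperCallSet(mapper_id=mapper_id, meta="methratio")
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if lineno == 1 and line.split("\t")[0].lower() in ("chr", "chrom", "chromosome"):
                continue
            f = _split(line, str(path), lineno, 8)
            chrom, pos_s, strand, context = f[0], f[1], f[2], f[3]
            if strand not in ("+", "-"):
                raise CallFormatError(f"bad strand {strand!r}", str(path), lineno)
            n_meth = _to_int(f[6], "C_count", str(path), lineno)
            depth = int(round(float(f[7])))
            if depth < n_meth:
                raise DataIntegrityError(
                    f"CT_count {depth} < C_count {n_meth} at {path}:{lineno}"
                )
            cs.add(
                CytosineCall(
                    chrom=chrom,
                    pos=_to_int(pos_s, "position", str(path), lineno),
                    strand=strand,
                    context=_normalize_context(context, str(path), lineno),
                    n_meth=n_meth,
                    n_unmeth=depth - n_meth,
                )
            )
    return cs


def _normalize_context(raw: str, path: str, lineno: int) -> str:
    """Map dialect context spellings (CG/CpG/CHG/CHH, methratio CG/CHG/CHH
    or 5-mer spellings) onto {CG, CHG, CHH}."""
    c = raw.upper().replace("P", "")  # CpG -> CG
    if c in CONTEXTS:
        return c
    # methratio may emit the 5-mer sequence context; classify by center+right
    if len(c) == 5 and c[2] == "C":
        if c[3] == "G":
            return "CG"
        if c[4] == "G":
            return "CHG"
        return "CHH"
    raise CallFormatError(f"unrecognized context {raw!r}", path, lineno)


def write_unified(callset: MapperCallSet, path: str | Path) -> None:
    """Write a call set to the unified TSV dialect (lossless round trip)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"#format={UNIFIED_FORMAT}\n")
        fh.write(f"#mapper_id={callset.mapper_id}\n")
        fh.write(f"#lam={callset.lam!r}\n")
        fh.write(f"#meta={callset.meta}\n")
        fh.write("#chrom\tpos\tstrand\tcontext\tn_meth\tn_unmeth\n")
        for call in sorted(callset, key=lambda c: c.key):
            fh.write(
                f"{call.chrom}\t{call.pos}\t{call.strand}\t{call.context}"
                f"\t{call.n_meth}\t{call.n_unmeth}\n"
            )


def read_unified(path: str | Path) -> MapperCallSet:
    """Read a unified TSV produced by :func:`write_unified`."""
    path = Path(path)
    header: dict[str, str] = {}
    cs: MapperCallSet | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#"):
                if "=" in line:
                    key, _, value = line[1:].rstrip("\n").partition("=")
                    header[key] = value
                continue
            if cs is None:
                cs = _callset_from_header(header, str(path))
            if not line.strip():
                continue
            f = _split(line, str(path), lineno, 6)
            cs.add(
                CytosineCall(
                    chrom=f[0],
                    pos=_to_int(f[1], "position", str(path), lineno),
                    strand=f[2],
                    context=_normalize_context(f[3], str(path), lineno),
                    n_meth=_to_int(f[4], "methylated count", str(path), lineno),
                    n_unmeth=_to_int(f[5], "unmethylated count", str(path), lineno),
                )
            )
    if cs is None:
        cs = _callset_from_header(header, str(path))
    return cs


def _callset_from_header(header: dict[str, str], path: str) -> MapperCallSet:
    if header.get("format") != UNIFIED_FORMAT:
        raise CallFormatError(
            f"not a {UNIFIED_FORMAT} file (format={header.get('format')!r})", path=path
        )
    return MapperCallSet(
        mapper_id=header.get("mapper_id", ""),
        lam=float(header.get("lam", "0")),
        meta=header.get("meta", ""),
    )


def estimate_lambda(
    callset: MapperCallSet,
    n_reference_cytosines: int,
    covered_only: bool = False,
) -> float:
    """Mean read depth of a mapper over the reference cytosines.

    By default the denominator is the number of ALL reference cytosine
    positions of the analyzed context set, so positions the mapper never
    covered contribute depth zero ("average read depth over whole genome").
    With ``covered_only=True`` the mean is taken over covered positions only.
    """
    if covered_only:
        if len(callset) == 0:
            return 0.0
        return sum(c.depth for c in callset) / len(callset)
    if n_reference_cytosines < 1:
        raise UsageError("n_reference_cytosines must be >= 1")
    if len(callset) > n_reference_cytosines:
        raise UsageError(
            f"call set has {len(callset)} positions but the reference "
            f"only {n_reference_cytosines}"
        )
    return sum(c.depth for c in callset) / n_reference_cytosines


READERS = {
    "cgmap": read_cgmap,
    "bismark-report": read_bismark_report,
    "bismark-cov": read_bismark_cov,
    "methratio": read_methratio,
    "unified": read_unified,
}


def sniff_format(path: str | Path) -> str:
    """Guess the dialect of a call file from its first non-empty line."""
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip():
                first = line
                break
    if first.startswith(f"#format={UNIFIED_FORMAT}"):
        return "unified"
    f = first.rstrip("\n").split("\t")
    if len(f) >= 8 and f[1] in ("C", "G"):
        return "cgmap"
    if len(f) >= 8 and f[2] in ("+", "-"):
        return "methratio"
    if len(f) >= 7 and f[2] in ("+", "-"):
        return "bismark-report"
    if len(f) == 6:
        return "bismark-cov"
    raise CallFormatError("cannot identify call-file dialect", path=str(path))


def read_calls(path: str | Path, fmt: str = "auto", mapper_id: str | None = None) -> MapperCallSet:
    """Read a call file, sniffing the dialect when ``fmt='auto'``."""
    if fmt == "auto":
        fmt = sniff_format(path)
    try:
        reader = READERS[fmt]
    except KeyError:
        raise UsageError(f"unknown call format {fmt!r}") from None
    if fmt == "unified":
        cs = reader(path)
        if mapper_id is not None:
            cs.mapper_id = mapper_id
        return cs
    if mapper_id is None:
        return reader(path)
    return reader(path, mapper_id=mapper_id)
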