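"""Quadripartite plastome architecture: inverted-repeat detection, per-region
GC content, and IR/SC junction profiling.

A chloroplast genome is circular with four regions in the order
LSC-IRb-SSC-IRa, where IRb and IRa are exact reverse complements of each
other.  The four junctions are named J_LB (LSC/IRb), J_SB (IRb/SSC),
J_SA (SSC/IRa) and J_LA (IRa/LSC).  Genes bisected by a junction leave a
duplicated pseudogene fragment in the other IR copy: rpl22 spanning J_LB
yields a psi-rpl22 fragment at J_LA, and ycf1 spanning J_SA yields a
psi-ycf1 fragment that abuts J_SB from inside IRb.  Whether ndhF (which sits
at the IRb-proximal end of the SSC) reaches into that psi-ycf1 fragment is
the overlap-vs-gap distinction at J_SB.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .formats_io import (
    GenomeInterval,
    PlastomeRecord,
    ValidationError,
    revcomp,
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class NoInvertedRepeatError(ValidationError):
    """No reverse-complement repeat of the required length was found."""


class AmbiguousRepeatError(ValidationError):
    """Several distinct maximal repeat pairs tie for the longest length."""


@dataclass(frozen=True)
class QuadripartitePartition:
    """The four region intervals of one plastome, in canonical coordinates.

    Canonical coordinates start at the first LSC base (the base following
    J_LA), so lsc.start == 0 and the regions tile the genome in the order
    LSC-IRb-SSC-IRa.  `origin` records where canonical position 0 sits in
    the coordinate system of the sequence handed to the detector; it is 0
    when the input was already canonically rotated.
    """

    lsc: GenomeInterval
    irb: GenomeInterval
    ssc: GenomeInterval
    ira: GenomeInterval
    origin: int = 0

    def __post_init__(self) -> None:
        if self.lsc.start != 0:
            raise ValidationError("canonical partition must start with LSC at 0")
        if not (
            self.lsc.end == self.irb.start
            and self.irb.end == self.ssc.start
            and self.ssc.end == self.ira.start
        ):
            raise ValidationError("regions must tile the genome contiguously")
        if self.irb.length != self.ira.length:
            raise ValidationError("IR copies must have equal length")
        if self.lsc.length <= self.ssc.length:
            raise ValidationError("LSC must be longer than SSC")

    @property
    def genome_length(self) -> int:
        return self.ira.end

    @property
    def ir_length(self) -> int:
        return self.irb.length

    def region_of(self, pos: int) -> str:
        """Region label for a canonical coordinate; both IR copies -> 'IR'."""
        if self.lsc.contains(pos):
            return "LSC"
        if self.ssc.contains(pos):
            return "SSC"
        if self.irb.contains(pos) or self.ira.contains(pos):
            return "IR"
        raise ValidationError(f"position {pos} outside genome of length {self.genome_length}")

    def validate_sequence(self, sequence: str) -> None:
        """Check tiling and the IRb == revcomp(IRa) identity on a canonical sequence."""
        if len(sequence) != self.genome_length:
            raise ValidationError(
                f"partition covers {self.genome_length} bp but sequence is "
                f"{len(sequence)} bp"
            )
        irb = sequence[self.irb.start : self.irb.end]
        ira = sequence[self.ira.start : self.ira.end]
        if irb != revcomp(ira):
            raise ValidationError("IRb is not the reverse complement of IRa")


@dataclass(frozen=True)
class JunctionProfile:
    """Junction coordinates and pseudogene fragment lengths (canonical coords).

    ndhf_jsb_offset is the signed distance J_SB minus ndhF's junction-proximal
    end: positive values mean ndhF extends into IRb and overlaps the psi-ycf1
    fragment by that many bp; zero or negative values mean a gap of that size
    (a 0 bp gap counts as the gap type).
    """

    j_lb: int
    j_sb: int
    j_sa: int
    j_la: int
    psi_rpl22_len: int | None = None
    psi_ycf1_len: int | None = None
    ndhf_jsb_offset: int | None = None

    @property
    def jsb_type(self) -> str:
        return classify_jsb(self)


@dataclass(frozen=True)
class RegionGC:
    """GC content in percent, per region; `ir` is computed on one IR copy."""

    total: float | None
    lsc: float | None
    ssc: float | None
    ir: float | None


# ---------------------------------------------------------------------------
# IR detection


def _find_repeat_candidates(sequence: str, min_ir_len: int, seed_len: int):
    """Maximal disjoint reverse-complement repeat pairs on the circle.

    Seeds exact seed_len-mers against their reverse complements in the
    doubled sequence, then extends each seed maximally.  All seeds of one
    repeat pair share the anti-diagonal constant a1 + b2 (left occurrence
    start plus right occurrence end), so extensions are deduplicated on it.
    Returns a list of (startA, startB, length) with starts mod n.
    """
    n = len(sequence)
    doubled = sequence + sequence
    comp = doubled.translate(_COMPLEMENT)

    index: dict[str, list[int]] = {}
    for p in range(n):
        index.setdefault(doubled[p : p + seed_len], []).append(p)

    covered: dict[int, list[tuple[int, int]]] = {}
    max_len = n // 2
    candidates: dict[tuple[int, int, int], None] = {}

    for p in range(n):
        kmer = doubled[p : p + seed_len]
        rk = revcomp(kmer)
        for q in index.get(rk, ()):
            c = p + q + seed_len  # anti-diagonal invariant a1 + b2
            spans = covered.setdefault(c, [])
            if any(lo <= p < hi for lo, hi in spans):
                continue
            a1, a2 = p, p + seed_len
            b1, b2 = q, q + seed_len
            # extend left of A / right of B
            while (
                a1 > 0
                and b2 < 2 * n
                and a2 - a1 < max_len
                and doubled[a1 - 1] == comp[b2]
            ):
                a1 -= 1
                b2 += 1
            # extend right of A / left of B
            while (
                a2 < 2 * n
                and b1 > 0
                and a2 - a1 < max_len
                and doubled[a2] == comp[b1 - 1]
            ):
                a2 += 1
                b1 -= 1
            length = a2 - a1
            spans.append((a1, a2))
            if length < min_ir_len:
                continue
            sa, sb = a1 % n, b1 % n
            # disjoint arcs on the circle?
            occ = sorted([(sa, length), (sb, length)])
            (s1, l1), (s2, l2) = occ
            if s2 < s1 + l1 or s2 + l2 > s1 + n:
                continue  # overlapping arcs (e.g. a palindrome with itself)
            candidates[(s1, s2, length)] = None
    return list(candidates)


def detect_inverted_repeat(
    sequence: str, min_ir_len: int = 1000, seed_len: int = 20
) -> QuadripartitePartition:
    """Detect the quadripartite architecture of a circular plastome.

    Finds the longest pair of disjoint exact reverse-complement repeats of at
    least min_ir_len bp and derives the canonical LSC-IRb-SSC-IRa partition,
    with |LSC| > |SSC| and IRb defined as the IR copy adjacent to the 3' end
    of the LSC.  The returned partition's `origin` gives the rotation that
    maps the input to canonical coordinates (see `canonicalize_record`).
    """
    sequence = sequence.upper()
    n = len(sequence)
    if n <= 2 * min_ir_len:
        raise ValidationError(
            f"sequence of {n} bp too short for min_ir_len={min_ir_len}"
        )
    seed_len = min(seed_len, min_ir_len)
    candidates = _find_repeat_candidates(sequence, min_ir_len, seed_len)
    if not candidates:
        raise NoInvertedRepeatError(
            f"no inverted repeat of >= {min_ir_len} bp found"
        )
    best_len = max(length for _, _, length in candidates)
    best = sorted(c for c in candidates if c[2] == best_len)
    if len(best) > 1:
        raise AmbiguousRepeatError(
            f"ambiguous IR: {len(best)} distinct maximal repeat pairs of "
            f"{best_len} bp: {best}"
        )
    s1, s2, length = best[0]
    gap12 = (s2 - (s1 + length)) % n  # arc from end of occ1 to start of occ2
    gap21 = (s1 - (s2 + length)) % n
    if gap12 == gap21:
        raise AmbiguousRepeatError(
            "single-copy regions have equal length; LSC/SSC orientation ambiguous"
        )
    if min(gap12, gap21) == 0:
        raise ValidationError("degenerate architecture: empty single-copy region")
    if gap12 > gap21:
        lsc_len, ssc_len = gap12, gap21
        origin = (s1 + length) % n  # LSC follows occurrence 1; IRb is occ2
    else:
        lsc_len, ssc_len = gap21, gap12
        origin = (s2 + length) % n
    partition = QuadripartitePartition(
        lsc=GenomeInterval(0, lsc_len),
        irb=GenomeInterval(lsc_len, lsc_len + length),
        ssc=GenomeInterval(lsc_len + length, lsc_len + length + ssc_len),
        ira=GenomeInterval(lsc_len + length + ssc_len, n),
        origin=origin,
    )
    partition.validate_sequence(sequence[origin:] + sequence[:origin])
    return partition


def canonicalize_record(
    record: PlastomeRecord, partition: QuadripartitePartition
) -> tuple[PlastomeRecord, QuadripartitePartition]:
    """Rotate a record so the partition's canonical coordinates apply directly.

    Gene intervals are shifted by the same rotation; a gene that would wrap
    the new origin (i.e. spans J_LA after rotation) is not representable as a
    single interval and raises a ValidationError.
    """
    origin = partition.origin
    if origin == 0:
        return record, partition
    n = len(record.sequence)
    seq = record.sequence[origin:] + record.sequence[:origin]
    genes: dict[str, GenomeInterval] = {}
    for name, iv in record.genes.items():
        start = (iv.start - origin) % n
        end = start + iv.length
        if end > n:
            raise ValidationError(
                f"gene {name} spans the canonical origin after rotation"
            )
        genes[name] = GenomeInterval(start, end, iv.strand)
    rotated = PlastomeRecord(
        id=record.id, sequence=seq, genes=genes, category=record.category
    )
    canon = QuadripartitePartition(
        lsc=partition.lsc,
        irb=partition.irb,
        ssc=partition.ssc,
        ira=partition.ira,
        origin=0,
    )
    return rotated, canon


# ---------------------------------------------------------------------------
# GC content


def _gc_percent(seq: str) -> float | None:
    gc = seq.count("G") + seq.count("C")
    denom = gc + seq.count("A") + seq.count("T")  # N excluded from both sides
    if denom == 0:
        return None
    return 100.0 * gc / denom


def gc_by_region(record: PlastomeRecord, partition: QuadripartitePartition) -> RegionGC:
    """GC% overall and per region; N bases excluded from numerator and
    denominator; an all-N region is reported as missing (None)."""
    record, partition = canonicalize_record(record, partition)
    partition.validate_sequence(record.sequence)
    seq = record.sequence
    return RegionGC(
        total=_gc_percent(seq),
        lsc=_gc_percent(seq[partition.lsc.start : partition.lsc.end]),
        ssc=_gc_percent(seq[partition.ssc.start : partition.ssc.end]),
        ir=_gc_percent(seq[partition.irb.start : partition.irb.end]),
    )


# ---------------------------------------------------------------------------
# Junction profiling


def profile_junctions(
    record: PlastomeRecord, partition: QuadripartitePartition
) -> JunctionProfile:
    """Measure the pseudogene fragments and the J_SB offset of one plastome.

    psi_rpl22_len = bp of rpl22 inside IRb (rpl22 spans J_LB);
    psi_ycf1_len  = bp of ycf1 inside IRa (ycf1 spans J_SA; the IR duplicates
    that 5' portion into IRb, where it abuts J_SB);
    ndhf_jsb_offset = J_SB minus ndhF's junction-proximal end, i.e. the
    signed overlap of ndhF with the psi-ycf1 fragment at J_SB (positive =
    overlap, zero/negative = gap).  Missing genes yield None fields; a gene
    annotated entirely in the wrong region yields 0 with a warning.
    """
    record, partition = canonicalize_record(record, partition)
    profile_kwargs: dict[str, int | None] = {
        "psi_rpl22_len": None,
        "psi_ycf1_len": None,
        "ndhf_jsb_offset": None,
    }
    genes = record.genes
    if "rpl22" in genes:
        iv = genes["rpl22"]
        if iv.overlap(partition.lsc) == 0 and iv.overlap(partition.irb) == 0:
            warnings.warn("rpl22 annotated entirely outside LSC/IRb; psi_rpl22 set to 0")
            profile_kwargs["psi_rpl22_len"] = 0
        else:
            profile_kwargs["psi_rpl22_len"] = iv.overlap(partition.irb)
    if "ycf1" in genes:
        iv = genes["ycf1"]
        if iv.overlap(partition.ssc) == 0 and iv.overlap(partition.ira) == 0:
            warnings.warn("ycf1 annotated entirely outside SSC/IRa; psi_ycf1 set to 0")
            profile_kwargs["psi_ycf1_len"] = 0
        else:
            profile_kwargs["psi_ycf1_len"] = iv.overlap(partition.ira)
    if "ndhF" in genes:
        iv = genes["ndhF"]
        if iv.overlap(partition.ssc) == 0 and iv.overlap(partition.irb) == 0:
            warnings.warn("ndhF annotated entirely outside SSC/IRb; offset set to 0")
            profile_kwargs["ndhf_jsb_offset"] = 0
        else:
            j_sb = partition.irb.end
            proximal = iv.start if abs(iv.start - j_sb) <= abs(iv.end - j_sb) else iv.end
            profile_kwargs["ndhf_jsb_offset"] = j_sb - proximal
    return JunctionProfile(
        j_lb=partition.lsc.end,
        j_sb=partition.irb.end,
        j_sa=partition.ssc.end,
        j_la=partition.ira.end,
        **profile_kwargs,
    )


def classify_jsb(profile: JunctionProfile) -> str:
    """Type the SSC/IRb junction: 'type_a_overlap' when ndhF overlaps the
    psi-ycf1 fragment (offset > 0), 'type_b_gap' for a 0+ bp gap (offset <= 0),
    'undetermined' when the offset could not be measured."""
    if profile.ndhf_jsb_offset is None:
        return "undetermined"
    return "type_a_overlap" if profile.ndhf_jsb_offset > 0 else "type_b_gap"
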