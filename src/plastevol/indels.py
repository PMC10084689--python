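"""Reference-anchored InDel calling from a multiple alignment, region
assignment, per-region densities (bp/kbp) and per-branch accumulation rates
(bp/myr) on a dated tree.

Each sample row is compared pairwise with the reference row on the given
alignment's columns: columns where both rows have gaps carry no information
for that pair and are skipped (the standard pairwise projection of an MSA),
and terminal gap runs are trimmed before calling.  A maximal run of columns
where the sample has residues over reference gaps is one insertion; the
converse is one deletion.  Adjacent insertion and deletion runs are reported
as separate events, never merged into substitutions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .formats_io import GAP_CHARS, PlastevolError, FormatError, ValidationError, DatedTree
from .structure import QuadripartitePartition

REGIONS = ("LSC", "IR", "SSC")


@dataclass(frozen=True)
class IndelEvent:
    """One insertion or deletion of a sample relative to the reference.

    ref_pos is the 0-based reference coordinate of the run's left flank
    (-1 for an insertion before the first reference base after trimming);
    length is the event's size in bp.
    """

    sample_id: str
    kind: str  # "insertion" | "deletion"
    ref_pos: int
    length: int
    region: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("insertion", "deletion"):
            raise ValidationError(f"bad indel kind {self.kind!r}")
        if self.length < 1:
            raise ValidationError("indel length must be >= 1")
        if self.ref_pos < -1:
            raise ValidationError("ref_pos must be >= -1")


@dataclass(frozen=True)
class RatePerBranch:
    """InDel accumulation rates (bp/myr) along one branch of the dated tree."""

    branch_id: str
    duration_myr: float
    insertion_bp: int
    deletion_bp: int

    @property
    def insertion_rate(self) -> float:
        return self.insertion_bp / self.duration_myr

    @property
    def deletion_rate(self) -> float:
        return self.deletion_bp / self.duration_myr


def _nongap_span(row: str) -> tuple[int, int]:
    first = next((i for i, ch in enumerate(row) if ch not in GAP_CHARS), len(row))
    last = next((i for i in range(len(row) - 1, -1, -1) if row[i] not in GAP_CHARS), -1)
    return first, last + 1


def call_indels(
    alignment: list[tuple[str, str]], reference_id: str
) -> list[IndelEvent]:
    """Call InDels for every sample in the alignment against the reference.

    Returns events in alignment-column order per sample, samples in input
    order.  Raises if the reference is absent or rows differ in length.
    """
    rows = dict(alignment)
    if len(rows) != len(alignment):
        raise ValidationError("duplicate sequence ids in alignment")
    if reference_id not in rows:
        raise PlastevolError(f"reference {reference_id!r} not in alignment")
    lengths = {len(seq) for _, seq in alignment}
    if len(lengths) > 1:
        raise FormatError(f"alignment rows of unequal length: {sorted(lengths)}")
    ref = rows[reference_id]
    events: list[IndelEvent] = []
    for sample_id, row in alignment:
        if sample_id == reference_id:
            continue
        events.extend(_call_pair(ref, row, sample_id))
    return events


def _call_pair(ref: str, sample: str, sample_id: str) -> list[IndelEvent]:
    # terminal trimming is per sample row: a sample's leading/trailing gap
    # runs are alignment-end artifacts, not deletions; reference-side
    # terminal gaps inside the window remain callable insertions (ref_pos -1)
    lo, hi = _nongap_span(sample)
    # reference coordinate bookkeeping counts residues from column 0 so that
    # positions stay in full reference coordinates even if the window trims
    # reference residues (a sample shorter than the reference at the ends).
    ref_seen = sum(1 for ch in ref[:lo] if ch not in GAP_CHARS)
    events: list[IndelEvent] = []
    run_kind: str | None = None
    run_len = 0
    run_left_flank = -1

    def close_run() -> None:
        nonlocal run_kind, run_len
        if run_kind is not None:
            events.append(
                IndelEvent(sample_id, run_kind, run_left_flank, run_len)
            )
        run_kind, run_len = None, 0

    for col in range(lo, hi):
        r_gap = ref[col] in GAP_CHARS
        s_gap = sample[col] in GAP_CHARS
        if r_gap and s_gap:
            continue  # uninformative for this pair; transparent to runs
        if not r_gap and not s_gap:
            close_run()
            ref_seen += 1
        elif r_gap:  # sample residue over reference gap: insertion
            if run_kind != "insertion":
                close_run()
                run_kind = "insertion"
                run_left_flank = ref_seen - 1
            run_len += 1
        else:  # reference residue over sample gap: deletion
            if run_kind != "deletion":
                close_run()
                run_kind = "deletion"
                run_left_flank = ref_seen - 1
            run_len += 1
            ref_seen += 1
    close_run()
    return events


def assign_region(
    event: IndelEvent, reference_partition: QuadripartitePartition
) -> IndelEvent:
    """Label an event with the reference region containing its left flank.

    Both IR copies map to the single label 'IR'.  An insertion before the
    first reference base (ref_pos -1) is assigned to the region containing
    reference base 0.  The left-flank rule means an event anchored at the
    last base of a region belongs to that region.
    """
    pos = max(event.ref_pos, 0)
    return replace(event, region=reference_partition.region_of(pos))


def assign_regions(
    events: list[IndelEvent], reference_partition: QuadripartitePartition
) -> list[IndelEvent]:
    return [assign_region(e, reference_partition) for e in events]


def summarize_indels(events: list[IndelEvent]) -> pd.DataFrame:
    """Aggregate event bp per (sample, kind, region) into a tidy table."""
    rows = [
        {
            "sample_id": e.sample_id,
            "kind": e.kind,
            "region": e.region,
            "n_events": 1,
            "bp": e.length,
        }
        for e in events
    ]
    if not rows:
        return pd.DataFrame(
            columns=["sample_id", "kind", "region", "n_events", "bp"]
        )
    df = pd.DataFrame(rows)
    return (
        df.groupby(["sample_id", "kind", "region"], dropna=False, sort=True)
        .sum()
        .reset_index()
    )


def indel_density(
    summary: pd.DataFrame, partition: QuadripartitePartition
) -> pd.DataFrame:
    """Per-sample, per-kind, per-region density in bp per kbp of region.

    Region lengths come from the reference partition; the IR length counts
    both copies, matching the pooling of both copies under the 'IR' label.
    """
    region_len = {
        "LSC": partition.lsc.length,
        "SSC": partition.ssc.length,
        "IR": partition.irb.length + partition.ira.length,
    }
    out = summary.copy()
    if out.empty:
        out["density_bp_per_kbp"] = pd.Series(dtype=float)
        return out
    out["density_bp_per_kbp"] = [
        1000.0 * bp / region_len[region]
        for bp, region in zip(out["bp"], out["region"])
    ]
    return out


def branch_rates(
    events_by_sample: dict[str, list[IndelEvent]],
    dated_tree: DatedTree,
    attribution: str = "terminal",
) -> list[RatePerBranch]:
    """InDel bp/myr per branch; v1 assigns all of a tip's events to its
    terminal branch (shared events are not parsimony-placed on internal
    branches)."""
    if attribution != "terminal":
        raise ValidationError(f"unsupported attribution {attribution!r}")
    tips = set(dated_tree.tip_labels)
    rates = []
    for sample_id, events in events_by_sample.items():
        if sample_id not in tips:
            raise ValidationError(f"sample {sample_id!r} is not a tip of the tree")
        duration = dated_tree.terminal_duration(sample_id)
        if duration <= 0:
            raise ValidationError(f"zero-duration branch for tip {sample_id!r}")
        ins = sum(e.length for e in events if e.kind == "insertion")
        dels = sum(e.length for e in events if e.kind == "deletion")
        rates.append(
            RatePerBranch(
                branch_id=sample_id,
                duration_myr=duration,
                insertion_bp=ins,
                deletion_bp=dels,
            )
        )
    return rates


def events_to_frame(events: list[IndelEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": e.sample_id,
                "kind": e.kind,
                "ref_pos": e.ref_pos,
                "length": e.length,
                "region": e.region,
            }
            for e in events
        ],
        columns=["sample_id", "kind", "ref_pos", "length", "region"],
    )
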