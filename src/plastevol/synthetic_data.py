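"""Ground-truthed synthetic inputs for every pipeline stage.

The generator emulates the study system end to end: a quadripartite plastome
ancestor with junction-spanning genes (rpl22 across J_LB, ycf1 across J_SA,
ndhF at J_SB with a configurable signed offset), sequence evolution along an
ultrametric dated tree with category-specific substitution and InDel rates
(Poisson counts, geometric lengths), diurnal Pn traces with the
category-specific sign structure, per-gene codon alignments with
category-specific non-synonymous elevation, and locality-by-bioclim tables
in which one pathway group is shifted on precipitation-seasonality variables
and another on temperature variables.

Homology is tracked exactly: every InDel is drawn in ancestor (reference)
coordinates with a one-base spacing buffer between event footprints along
any root-to-tip path, so the emitted multiple alignment and the per-branch
event log are mutually consistent ground truth, and reference-anchored
calling can recover every implanted event exactly.  All output is fully
determined by the seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd

from .formats_io import (
    DatedTree,
    GenomeInterval,
    PlastomeRecord,
    ValidationError,
    dated_tree_from_string,
)
from .indels import IndelEvent, assign_regions
from .structure import QuadripartitePartition

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

# species of the study system with the pathway each diurnal Pn trace shows
DEFAULT_CATEGORIES: dict[str, str] = {
    "D_chrysotoxum": "C3",
    "D_longicornu": "C3",
    "D_chrysanthum": "C3",
    "D_thyrsiflorum": "C3",
    "D_lindleyi": "C3",
    "D_primulinum": "CAM",
    "D_terminale": "CAM",
    "D_acinaciforme": "CAM",
    "D_officinale": "C3-CAM",
    "D_nobile": "C3-CAM",
    "D_hercoglossum": "C3-CAM",
}

# genome-wide InDel accumulation rates, bp/myr, by pathway category
DEFAULT_INSERTION_RATES = {"C3": 86.53, "CAM": 88.26, "C3-CAM": 92.86}
DEFAULT_DELETION_RATES = {"C3": 51.48, "CAM": 93.27, "C3-CAM": 42.73}
DEFAULT_SUBSTITUTION_RATES = {"C3": 0.0018, "CAM": 0.0024, "C3-CAM": 0.0018}

# diurnal Pn plateau amplitudes (day, night), umol CO2 m^-2 s^-1
DEFAULT_PN_AMPLITUDES = {
    "C3": (2.0, -0.5),
    "CAM": (-0.5, 2.0),
    "C3-CAM": (1.2, 0.4),
}

PRECIP_SHIFT_VARS = ("bio14", "bio15", "bio17", "bio19")
TEMP_SHIFT_VARS = ("bio1", "bio5", "bio6", "bio9", "bio10", "bio11")

# plausible subtropical baselines for the 19 WorldClim variables
# (temperature in degrees C, bio4 = sd*100, bio3 unitless %, precipitation mm)
DEFAULT_BIOCLIM_MEANS = {
    "bio1": 18.0, "bio2": 9.0, "bio3": 45.0, "bio4": 550.0, "bio5": 29.0,
    "bio6": 5.0, "bio7": 24.0, "bio8": 22.0, "bio9": 12.0, "bio10": 24.0,
    "bio11": 8.0, "bio12": 1400.0, "bio13": 260.0, "bio14": 15.0,
    "bio15": 65.0, "bio16": 700.0, "bio17": 60.0, "bio18": 650.0,
    "bio19": 70.0,
}
DEFAULT_BIOCLIM_SDS = {
    "bio1": 1.5, "bio2": 0.8, "bio3": 3.0, "bio4": 60.0, "bio5": 1.5,
    "bio6": 1.8, "bio7": 2.0, "bio8": 1.5, "bio9": 2.0, "bio10": 1.5,
    "bio11": 1.8, "bio12": 150.0, "bio13": 35.0, "bio14": 6.0,
    "bio15": 8.0, "bio16": 90.0, "bio17": 15.0, "bio18": 85.0,
    "bio19": 18.0,
}

# 68 plastid protein-coding genes used for the codon-evolution stage
PLASTID_GENES = (
    "atpA atpB atpE atpF atpH atpI accD ccsA cemA clpP infA matK ndhA ndhB "
    "ndhC ndhD ndhE ndhF ndhG ndhH ndhI ndhJ ndhK petA petB petD petG petL "
    "petN psaA psaB psaC psaI psaJ psbA psbB psbC psbD psbE psbF psbH psbI "
    "psbJ psbK psbL psbM psbN psbT psbZ rbcL rpl2 rpl14 rpl16 rpl20 rpl22 "
    "rpl23 rpl32 rpl33 rpl36 rpoA rpoB rpoC1 rpoC2 rps2 rps3 rps4 rps7"
).split()
CAM_ELEVATED_GENES = ("clpP", "matK", "ycf1")


@dataclass
class SimulationConfig:
    """All knobs of the generator; the seed fully determines every output."""

    seed: int = 0
    # --- plastome architecture (toy scale by default; see fullsize_config)
    lsc_len: int = 8000
    ir_len: int = 2500
    ssc_len: int = 1500
    region_gc: dict[str, float] = field(
        default_factory=lambda: {"LSC": 0.35, "SSC": 0.305, "IR": 0.433}
    )
    # junction-spanning gene geometry (bp)
    rpl22_len: int = 400
    psi_rpl22: int = 39
    ycf1_len: int = 900
    psi_ycf1: int = 315
    ndhf_len: int = 700
    ndhf_jsb_offset: int = 10  # >0: ndhF reaches into IRb (overlap type)
    # --- tree & taxa
    categories: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORIES)
    )
    tree_newick: str | None = None  # None -> ultrametric star at root_age
    root_age_myr: float = 10.0
    reference_id: str = "REF"
    # --- molecular evolution along the tree
    insertion_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INSERTION_RATES)
    )
    deletion_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DELETION_RATES)
    )
    substitution_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBSTITUTION_RATES)
    )
    mean_indel_len: float = 25.0  # geometric length distribution, bp
    # --- diurnal Pn traces
    pn_amplitudes: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PN_AMPLITUDES)
    )
    pn_noise_frac: float = 0.2  # noise sd = frac * |plateau amplitude|
    pn_replicates: int = 10
    pn_sampling_hours: float = 2.0
    day_start_hour: float = 6.0
    day_end_hour: float = 18.0
    # --- climate matrices
    localities_per_species: int = 13
    bioclim_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BIOCLIM_MEANS)
    )
    bioclim_sds: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BIOCLIM_SDS)
    )
    precip_shift_sds: float = 12.0  # C3-CAM shift on PRECIP_SHIFT_VARS, in sds
    temp_shift_sds: float = 0.62  # C3 shift on TEMP_SHIFT_VARS, in sds
    # (CAM is shifted by -5/3 of the C3 temperature shift so the temperature
    # contrast is orthogonal to the C3-CAM precipitation indicator under the
    # 5/3/3 species split; C3-CAM sits at the baseline temperature)
    # --- codon alignments
    codon_genes: tuple[str, ...] = tuple(PLASTID_GENES + ["ycf1"])  # 68 genes
    codons_per_gene: int = 60
    n_high_ds_genes: int = 35
    p_syn_fast: float = 0.30  # per-codon synonymous change prob, high-ds genes
    p_syn_slow: float = 0.05
    p_nonsyn: float = 0.02
    cam_dn_multiplier: float = 3.0
    cam_elevated_genes: tuple[str, ...] = CAM_ELEVATED_GENES

    def __post_init__(self) -> None:
        if min(self.lsc_len, self.ir_len) <= 0 or self.ssc_len <= 0:
            raise ValidationError("region lengths must be positive")
        if self.lsc_len <= self.ssc_len:
            raise ValidationError("LSC must be longer than SSC")
        for rates in (self.insertion_rates, self.deletion_rates, self.substitution_rates):
            if any(v < 0 for v in rates.values()):
                raise ValidationError("rates must be >= 0")
        if self.mean_indel_len < 1:
            raise ValidationError("mean InDel length must be >= 1 bp")
        if not (0 < self.psi_rpl22 < self.ir_len and 0 < self.psi_ycf1 < self.ir_len):
            raise ValidationError("pseudogene fragments must fit inside the IR")
        if self.rpl22_len <= self.psi_rpl22 or self.ycf1_len <= self.psi_ycf1:
            raise ValidationError("gene lengths must exceed their IR fragments")
        bad = set(self.categories.values()) - {"C3", "CAM", "C3-CAM"}
        if bad:
            raise ValidationError(f"unknown categories {sorted(bad)}")

    @property
    def genome_length(self) -> int:
        return self.lsc_len + 2 * self.ir_len + self.ssc_len

    @property
    def species(self) -> list[str]:
        return list(self.categories)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def toy_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Fast ~14.5 kb architecture for tests; evolutionary rates unchanged."""
    return SimulationConfig(seed=seed, **overrides)


def fullsize_config(seed: int = 0, **overrides) -> SimulationConfig:
    """~151 kb architecture with region sizes and GC echoing the study system."""
    defaults = dict(
        lsc_len=84_849,
        ir_len=26_300,
        ssc_len=14_157,
        region_gc={"LSC": 0.3508, "SSC": 0.3021, "IR": 0.4338},
        rpl22_len=430,
        ycf1_len=5_600,
        ndhf_len=2_240,
    )
    defaults.update(overrides)
    return SimulationConfig(seed=seed, **defaults)


# ---------------------------------------------------------------------------
# Ancestor construction


def _random_region(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))


def make_ancestor(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[PlastomeRecord, QuadripartitePartition]:
    """Build the ancestral plastome with exact IR copies and junction genes.

    The sequence is random with per-region GC; IRa is the exact reverse
    complement of IRb.  The four bases flanking the IR pair are adjusted so
    that the repeat is maximal exactly at the configured boundaries (the
    detector recovers the implanted architecture bp-exactly).  Genes: rpl22
    spans J_LB with psi_rpl22 bp inside IRb; ycf1 spans J_SA with psi_ycf1
    bp inside IRa; ndhF's junction-proximal end sits ndhf_jsb_offset bp
    before (positive: inside IRb) J_SB.
    """
    rng = config.rng() if rng is None else rng
    lsc = _random_region(rng, config.lsc_len, config.region_gc["LSC"])
    irb = _random_region(rng, config.ir_len, config.region_gc["IR"])
    ssc = _random_region(rng, config.ssc_len, config.region_gc["SSC"])
    ira = "".join(_COMP[b] for b in reversed(irb))
    seq = list(lsc + irb + ssc + ira)
    n = len(seq)
    j_lb = config.lsc_len
    j_sb = j_lb + config.ir_len
    j_sa = j_sb + config.ssc_len
    # forbid accidental IR extension beyond the configured boundaries:
    # left of IRb pairs with the first LSC base (circular wrap past J_LA),
    # right of IRb pairs with the last SSC base
    if seq[j_lb - 1] == _COMP[seq[0]]:
        seq[j_lb - 1] = next(b for b in "ACGT" if b != _COMP[seq[0]])
    if seq[j_sb] == _COMP[seq[j_sa - 1]]:
        seq[j_sb] = next(b for b in "ACGT" if b != _COMP[seq[j_sa - 1]])

    genes: dict[str, GenomeInterval] = {}
    genes["rpl22"] = GenomeInterval(
        j_lb - (config.rpl22_len - config.psi_rpl22), j_lb + config.psi_rpl22, "-"
    )
    ndhf_start = j_sb - config.ndhf_jsb_offset
    genes["ndhF"] = GenomeInterval(ndhf_start, ndhf_start + config.ndhf_len, "-")
    genes["ycf1"] = GenomeInterval(
        j_sa - (config.ycf1_len - config.psi_ycf1), j_sa + config.psi_ycf1, "+"
    )
    if genes["rpl22"].start < 0:
        raise ValidationError("rpl22 body does not fit in the LSC")
    if genes["ndhF"].start <= j_lb or genes["ndhF"].end >= genes["ycf1"].start:
        raise ValidationError("ndhF does not fit between J_SB and ycf1")
    if genes["ycf1"].end > n:
        raise ValidationError("ycf1 fragment does not fit in the IRa")

    record = PlastomeRecord(id=config.reference_id, sequence="".join(seq), genes=genes)
    partition = QuadripartitePartition(
        lsc=GenomeInterval(0, j_lb),
        irb=GenomeInterval(j_lb, j_sb),
        ssc=GenomeInterval(j_sb, j_sa),
        ira=GenomeInterval(j_sa, n),
    )
    return record, partition


# ---------------------------------------------------------------------------
# Evolution along the dated tree


def make_tree(config: SimulationConfig) -> DatedTree:
    """The configured tree, or an ultrametric star over all species."""
    if config.tree_newick is not None:
        return dated_tree_from_string(config.tree_newick)
    tips = ",".join(f"{sp}:{config.root_age_myr}" for sp in config.species)
    return dated_tree_from_string(f"({tips});")


@dataclass
class _Lineage:
    deleted: set[int] = field(default_factory=set)
    insertions: dict[int, tuple[int, str]] = field(default_factory=dict)
    substitutions: dict[int, str] = field(default_factory=dict)
    blocked: set[int] = field(default_factory=set)

    def copy(self) -> "_Lineage":
        return _Lineage(
            set(self.deleted),
            dict(self.insertions),
            dict(self.substitutions),
            set(self.blocked),
        )


@dataclass
class SimulationResult:
    """Everything a downstream test needs: sequences, true alignment, logs."""

    config: SimulationConfig
    ancestor: PlastomeRecord
    partition: QuadripartitePartition
    tree: DatedTree
    categories: dict[str, str]
    tip_records: dict[str, PlastomeRecord]
    alignment: list[tuple[str, str]]  # reference row first
    events_by_branch: dict[str, list[IndelEvent]]
    events_by_tip: dict[str, list[IndelEvent]]  # cumulative along the path


def _branch_category(node, categories: dict[str, str]) -> str:
    """Category used for a branch's rates: the first descendant tip's, in
    label order (exact for terminal branches; a convention for internal ones)."""
    tips = sorted(leaf.taxon.label for leaf in node.leaf_iter())
    return categories[tips[0]]


def _draw_indel_events(
    rng: np.random.Generator,
    lineage: _Lineage,
    branch_id: str,
    category: str,
    duration: float,
    config: SimulationConfig,
    n: int,
    uid_counter: itertools.count,
) -> list[IndelEvent]:
    """Poisson numbers of deletions and insertions with geometric lengths,
    placed uniformly subject to the path-wide spacing constraint."""
    events: list[IndelEvent] = []
    p_geom = 1.0 / config.mean_indel_len
    specs = [
        ("deletion", config.deletion_rates[category]),
        ("insertion", config.insertion_rates[category]),
    ]
    for kind, bp_rate in specs:
        n_events = rng.poisson(bp_rate / config.mean_indel_len * duration)
        for _ in range(n_events):
            length = int(rng.geometric(p_geom))
            placed = False
            for _attempt in range(1000):
                if kind == "deletion":
                    if length > n - 4:
                        break
                    start = int(rng.integers(2, n - length - 1))
                    footprint = range(start - 1, start + length + 1)
                    if any(pos in lineage.blocked for pos in footprint) or any(
                        pos in lineage.deleted for pos in range(start, start + length)
                    ):
                        continue
                    lineage.deleted.update(range(start, start + length))
                    lineage.blocked.update(footprint)
                    events.append(IndelEvent(branch_id, "deletion", start - 1, length))
                else:
                    flank = int(rng.integers(1, n - 2))
                    if (
                        flank in lineage.blocked
                        or flank + 1 in lineage.blocked
                        or flank - 1 in lineage.blocked
                        or flank in lineage.deleted
                        or flank + 1 in lineage.deleted
                    ):
                        continue
                    bases = "".join(rng.choice(list("ACGT"), size=length))
                    lineage.insertions[next(uid_counter)] = (flank, bases)
                    lineage.blocked.update((flank - 1, flank, flank + 1))
                    events.append(IndelEvent(branch_id, "insertion", flank, length))
                placed = True
                break
            if not placed and not (kind == "deletion" and length > n - 4):
                raise ValidationError(
                    f"could not place a {length} bp {kind} on branch {branch_id}; "
                    "genome too crowded for the configured rates"
                )
    return events


def _apply_substitutions(
    rng: np.random.Generator,
    lineage: _Lineage,
    category: str,
    duration: float,
    config: SimulationConfig,
    ancestor_seq: str,
) -> None:
    n = len(ancestor_seq)
    n_subs = rng.poisson(config.substitution_rates[category] * n * duration)
    bases = "ACGT"
    for _ in range(n_subs):
        for _attempt in range(1000):
            pos = int(rng.integers(0, n))
            if pos not in lineage.deleted:
                break
        else:
            continue
        current = lineage.substitutions.get(pos, ancestor_seq[pos])
        alternatives = [b for b in bases if b != current]
        lineage.substitutions[pos] = str(rng.choice(alternatives))


def evolve_along_tree(
    config: SimulationConfig,
    ancestor: PlastomeRecord | None = None,
    partition: QuadripartitePartition | None = None,
    rng: np.random.Generator | None = None,
) -> SimulationResult:
    """Evolve the ancestor along the dated tree; emit tips, true alignment
    and the exact per-branch event log (reference coordinates).

    Events are drawn per branch (Poisson counts scaled by branch duration),
    inherited by all descendant tips, and logged with the reference
    coordinate of their left flank; the first/last two reference bases never
    host events, so terminal trimming cannot hide any.  Substitutions are
    applied to present reference bases only, never inside gap states.
    """
    rng = config.rng() if rng is None else rng
    if ancestor is None or partition is None:
        ancestor, partition = make_ancestor(config, rng)
    tree = make_tree(config)
    missing = set(tree.tip_labels) - set(config.categories)
    if missing:
        raise ValidationError(f"tips without category: {sorted(missing)}")
    seq = ancestor.sequence
    n = len(seq)
    uid_counter = itertools.count()
    events_by_branch: dict[str, list[IndelEvent]] = {}
    events_by_tip: dict[str, list[IndelEvent]] = {}
    tip_lineages: dict[str, _Lineage] = {}

    internal_ids = itertools.count(1)

    def recurse(node, lineage: _Lineage, inherited: list[IndelEvent]) -> None:
        for child in node.child_node_iter():
            child_lineage = lineage.copy()
            if child.is_leaf():
                branch_id = child.taxon.label
            else:
                branch_id = f"node{next(internal_ids)}"
            duration = float(child.edge.length or 0.0)
            category = _branch_category(child, config.categories)
            branch_events: list[IndelEvent] = []
            if duration > 0:
                branch_events = _draw_indel_events(
                    rng, child_lineage, branch_id, category, duration, config,
                    n, uid_counter,
                )
                _apply_substitutions(
                    rng, child_lineage, category, duration, config, seq
                )
            events_by_branch[branch_id] = assign_regions(branch_events, partition)
            path_events = inherited + events_by_branch[branch_id]
            if child.is_leaf():
                tip_lineages[child.taxon.label] = child_lineage
                events_by_tip[child.taxon.label] = [
                    dc_replace(e, sample_id=child.taxon.label) for e in path_events
                ]
            else:
                recurse(child, child_lineage, path_events)

    recurse(tree.tree.seed_node, _Lineage(), [])

    alignment = _build_alignment(seq, tree.tip_labels, tip_lineages, config.reference_id)
    tip_records = {
        tip: PlastomeRecord(
            id=tip,
            sequence=row.replace("-", ""),
            category=config.categories[tip],
        )
        for tip, row in alignment
        if tip != config.reference_id
    }
    return SimulationResult(
        config=config,
        ancestor=ancestor,
        partition=partition,
        tree=tree,
        categories=dict(config.categories),
        tip_records=tip_records,
        alignment=alignment,
        events_by_branch=events_by_branch,
        events_by_tip=events_by_tip,
    )


def _build_alignment(
    ref_seq: str,
    tip_labels: list[str],
    tip_lineages: dict[str, _Lineage],
    reference_id: str,
) -> list[tuple[str, str]]:
    """Assemble the true MSA: reference columns in order, insertion columns
    spliced after their left-flank reference position (stable uid order;
    independent insertions from different lineages are not homologous and
    occupy separate columns)."""
    n = len(ref_seq)
    ins_at: dict[int, list[tuple[int, int, str]]] = {}
    all_uids: dict[int, tuple[int, str]] = {}
    for lineage in tip_lineages.values():
        all_uids.update(lineage.insertions)
    for uid, (flank, bases) in all_uids.items():
        ins_at.setdefault(flank, []).append((uid, len(bases), bases))
    for flank in ins_at:
        ins_at[flank].sort()

    rows = {tip: [] for tip in tip_labels}
    ref_row: list[str] = []
    for pos in range(n):
        ref_row.append(ref_seq[pos])
        for tip in tip_labels:
            lineage = tip_lineages[tip]
            if pos in lineage.deleted:
                rows[tip].append("-")
            else:
                rows[tip].append(lineage.substitutions.get(pos, ref_seq[pos]))
        for uid, length, bases in ins_at.get(pos, ()):
            ref_row.append("-" * length)
            for tip in tip_labels:
                if uid in tip_lineages[tip].insertions:
                    rows[tip].append(bases)
                else:
                    rows[tip].append("-" * length)
    alignment = [(reference_id, "".join(ref_row))]
    alignment.extend((tip, "".join(rows[tip])) for tip in tip_labels)
    return alignment


# ---------------------------------------------------------------------------
# Diurnal Pn traces


def make_pn_traces(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Long-format diurnal traces: species, replicate, time, phase, pn.

    Each category follows its plateau signs (C3 positive by day, CAM
    positive by night, C3-CAM positive in both) with Gaussian noise of sd
    pn_noise_frac * |amplitude|; pn_replicates biological replicates per
    species sampled every pn_sampling_hours over 24 h.
    """
    rng = config.rng() if rng is None else rng
    times = np.arange(0.0, 24.0, config.pn_sampling_hours)
    rows = []
    for species, category in config.categories.items():
        day_amp, night_amp = config.pn_amplitudes[category]
        for rep in range(1, config.pn_replicates + 1):
            for t in times:
                is_day = config.day_start_hour <= t < config.day_end_hour
                amp = day_amp if is_day else night_amp
                sd = config.pn_noise_frac * abs(amp)
                pn = amp + (rng.normal(0.0, sd) if sd > 0 else 0.0)
                rows.append(
                    {
                        "species": species,
                        "replicate": rep,
                        "time": float(t),
                        "phase": "day" if is_day else "night",
                        "pn": pn,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Climate matrices


def make_climate(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Locality-by-bioclim table with the implanted group structure.

    13 localities per species by default (11 species -> 143 rows).  C3-CAM
    species are shifted on the precipitation-seasonality variables (bio14,
    bio15, bio17, bio19) by precip_shift_sds standard deviations; on the six
    temperature variables C3 species are shifted by +temp_shift_sds and CAM
    species by -5/3 * temp_shift_sds (C3-CAM at baseline), which makes the
    temperature contrast orthogonal to the precipitation indicator under the
    default 5/3/3 species split.  All other variables are pure noise around
    the baseline with a shared diagonal covariance.
    """
    rng = config.rng() if rng is None else rng
    if config.localities_per_species < 1:
        raise ValidationError("need at least one locality per species")
    if any(sd <= 0 for sd in config.bioclim_sds.values()):
        raise ValidationError("bioclim sds must be positive (diagonal covariance)")
    rows = []
    for species, category in config.categories.items():
        for loc in range(1, config.localities_per_species + 1):
            row: dict[str, object] = {
                "species": species,
                "locality": f"{species}_loc{loc:02d}",
                "lon": float(rng.uniform(97.0, 122.0)),
                "lat": float(rng.uniform(18.0, 34.0)),
            }
            for var, mean in config.bioclim_means.items():
                sd = config.bioclim_sds[var]
                shift = 0.0
                if var in PRECIP_SHIFT_VARS and category == "C3-CAM":
                    shift = config.precip_shift_sds * sd
                elif var in TEMP_SHIFT_VARS:
                    if category == "C3":
                        shift = config.temp_shift_sds * sd
                    elif category == "CAM":
                        shift = -(5.0 / 3.0) * config.temp_shift_sds * sd
                row[var] = float(mean + shift + rng.normal(0.0, sd))
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Codon alignments


def _random_codon(rng: np.random.Generator, stops: frozenset[str]) -> str:
    while True:
        codon = "".join(rng.choice(list("ACGT"), size=3))
        if codon not in stops:
            return codon


def make_codon_alignments(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> dict[str, list[tuple[str, str]]]:
    """Per-gene codon alignments of every taxon against the reference.

    Each gene's reference is a random stop-free codon sequence; each taxon's
    copy mutates codons independently: with probability p_syn a synonymous
    single-base change (when one exists), with probability p_nonsyn a
    non-synonymous single-base change avoiding stops.  Genes in the high-ds
    set use p_syn_fast (saturating ds, the screen's target); the remainder
    use p_syn_slow.  For cam_elevated_genes, CAM taxa multiply p_nonsyn by
    cam_dn_multiplier and C3 taxa halve it, implanting the category ranking
    dn(CAM) > dn(C3-CAM) > dn(C3).
    """
    from .codonevol import _AA, _STOPS

    rng = config.rng() if rng is None else rng
    genes = list(dict.fromkeys(config.codon_genes))
    # keep the elevated genes out of the screened (high-ds) set so the
    # category comparison still sees them after filtering
    eligible = [g for g in genes if g not in config.cam_elevated_genes]
    high_ds = set(eligible[: config.n_high_ds_genes])

    def synonymous_neighbors(codon: str) -> list[str]:
        out = []
        for pos in range(3):
            for alt in "ACGT":
                if alt == codon[pos]:
                    continue
                mut = codon[:pos] + alt + codon[pos + 1 :]
                if mut not in _STOPS and _AA[mut] == _AA[codon]:
                    out.append(mut)
        return out

    def nonsynonymous_neighbors(codon: str) -> list[str]:
        out = []
        for pos in range(3):
            for alt in "ACGT":
                if alt == codon[pos]:
                    continue
                mut = codon[:pos] + alt + codon[pos + 1 :]
                if mut not in _STOPS and _AA[mut] != _AA[codon]:
                    out.append(mut)
        return out

    result: dict[str, list[tuple[str, str]]] = {}
    for gene in genes:
        ref_codons = [
            _random_codon(rng, _STOPS) for _ in range(config.codons_per_gene)
        ]
        p_syn = config.p_syn_fast if gene in high_ds else config.p_syn_slow
        pairs: list[tuple[str, str]] = [(config.reference_id, "".join(ref_codons))]
        for taxon, category in config.categories.items():
            p_nonsyn = config.p_nonsyn
            if gene in config.cam_elevated_genes:
                if category == "CAM":
                    p_nonsyn *= config.cam_dn_multiplier
                elif category == "C3":
                    p_nonsyn *= 0.5
            taxon_codons = []
            for codon in ref_codons:
                mutated = codon
                if rng.random() < p_syn:
                    neigh = synonymous_neighbors(mutated)
                    if neigh:
                        mutated = neigh[int(rng.integers(0, len(neigh)))]
                if rng.random() < p_nonsyn:
                    neigh = nonsynonymous_neighbors(mutated)
                    if neigh:
                        mutated = neigh[int(rng.integers(0, len(neigh)))]
                taxon_codons.append(mutated)
            pairs.append((taxon, "".join(taxon_codons)))
        result[gene] = pairs
    return result


# ---------------------------------------------------------------------------
# Whole-bundle convenience


@dataclass
class Bundle:
    """One seed's worth of inputs for every pipeline stage."""

    simulation: SimulationResult
    pn_traces: pd.DataFrame
    climate: pd.DataFrame
    codon_alignments: dict[str, list[tuple[str, str]]]


def generate_bundle(config: SimulationConfig) -> Bundle:
    """Generate all stage inputs from one seed (single shared RNG stream)."""
    rng = config.rng()
    ancestor, partition = make_ancestor(config, rng)
    sim = evolve_along_tree(config, ancestor, partition, rng)
    pn = make_pn_traces(config, rng)
    climate = make_climate(config, rng)
    codon = make_codon_alignments(config, rng)
    return Bundle(
        simulation=sim, pn_traces=pn, climate=climate, codon_alignments=codon
    )
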