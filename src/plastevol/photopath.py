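"""Photosynthetic-pathway classification from diurnal net-photosynthesis
(Pn) traces.

The call is a sign rule on the day and night means of Pn (mean of replicate
means): a positive day mean with a non-positive night mean is C3 (net CO2
uptake only in the light); the mirrored pattern is CAM (nocturnal fixation);
positive means in both phases is the facultative C3-CAM intermediate; and
non-positive means in both phases leave the species undetermined.  Ties at
exactly zero resolve to the non-positive branch.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .formats_io import ValidationError

PHASES = ("day", "night")
REQUIRED_COLUMNS = ("species", "replicate", "time", "phase", "pn")


@dataclass(frozen=True)
class PathwayCall:
    """Classification of one species from its Pn trace."""

    species: str
    call: str  # C3 | CAM | C3-CAM | undetermined
    day_mean: float
    night_mean: float


def _sign_rule(day_mean: float, night_mean: float) -> str:
    if day_mean > 0 and night_mean <= 0:
        return "C3"
    if day_mean <= 0 and night_mean > 0:
        return "CAM"
    if day_mean > 0 and night_mean > 0:
        return "C3-CAM"
    return "undetermined"


def classify_pathway(trace: pd.DataFrame) -> PathwayCall:
    """Classify one species' diurnal trace.

    `trace` needs columns replicate, time, phase ('day'/'night'), pn and an
    identifying `species` column (one species only).  Phase means are
    computed per replicate first and then averaged across replicates, so
    unbalanced sampling within a replicate does not bias the call.
    """
    for col in REQUIRED_COLUMNS:
        if col not in trace.columns:
            raise ValidationError(f"Pn trace missing column {col!r}")
    species = trace["species"].unique()
    if len(species) != 1:
        raise ValidationError(f"expected one species per trace, got {list(species)}")
    bad_phase = set(trace["phase"].unique()) - set(PHASES)
    if bad_phase:
        raise ValidationError(f"unknown phase labels {sorted(bad_phase)}")
    if set(trace["phase"].unique()) != set(PHASES):
        raise ValidationError("trace needs at least one day and one night sample")
    times = trace["time"].astype(float)
    if ((times < 0) | (times >= 24)).any():
        raise ValidationError("times of day must lie in [0, 24)")
    rep_means = (
        trace.groupby(["replicate", "phase"])["pn"].mean().unstack("phase")
    )
    day_mean = float(rep_means["day"].mean())
    night_mean = float(rep_means["night"].mean())
    return PathwayCall(
        species=str(species[0]),
        call=_sign_rule(day_mean, night_mean),
        day_mean=day_mean,
        night_mean=night_mean,
    )


def classify_table(traces: pd.DataFrame) -> pd.DataFrame:
    """Classify every species in a long-format Pn table.

    Returns a table with columns species, day_mean, night_mean, call,
    ordered by species id.
    """
    calls = [
        classify_pathway(sub) for _, sub in traces.groupby("species", sort=True)
    ]
    return pd.DataFrame(
        [
            {
                "species": c.species,
                "day_mean": c.day_mean,
                "night_mean": c.night_mean,
                "call": c.call,
            }
            for c in calls
        ]
    )
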