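"""Multinomial bootstrap null for assemblage composition.

Tests whether per-subzone species compositions deviate from random sampling
of the overall assemblage: species names are drawn with replacement
``draw_n`` times (the mean per-subzone sample size, 29 for the packaged
occurrence data) with overall relative abundances as selection
probabilities; repeating this ``reps`` times (500 by default) yields, per
species, a min-max envelope of simulated relative abundances — the frame
within which observed changes in abundance can be considered random.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import OccurrenceTable


@dataclass
class CompositionEnvelope:
    """Bootstrap envelope of per-species relative abundances.

    ``envelope`` is a species x (min, max) frame; with
    ``percentiles=(lo, hi)`` the bounds are quantiles instead of the
    min-max range.
    """

    species_probabilities: pd.Series
    draw_n: int
    reps: int
    envelope: pd.DataFrame
    seed: int
    simulated: np.ndarray  # (reps, n_species) relative abundances


def default_draw_n(occurrences: OccurrenceTable) -> int:
    """Mean per-subzone specimen count, rounded half up (144/5 = 28.8 -> 29
    for the packaged table)."""
    total = occurrences.grand_total()
    n_subzones = len(occurrences.subzones)
    if total == 0 or n_subzones == 0:
        raise ValueError("empty occurrence table")
    return int(np.floor(total / n_subzones + 0.5))


def bootstrap_composition(
    overall_counts: pd.Series | dict[str, int],
    draw_n: int,
    reps: int = 500,
    seed: int = 0,
    percentiles: tuple[float, float] | None = None,
) -> CompositionEnvelope:
    """Simulate ``reps`` multinomial samples of size ``draw_n`` from the
    overall species relative abundances and record each species' envelope.

    Deterministic given ``seed``; replicates are drawn sequentially from a
    single stream, so increasing ``reps`` under the same seed extends the
    existing replicate set (the envelope widens monotonically).
    """
    counts = pd.Series(overall_counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("negative species counts")
    total = counts.sum()
    if total <= 0:
        raise ValueError("all species counts are zero")
    if draw_n < 1 or reps < 1:
        raise ValueError("draw_n and reps must be >= 1")
    probs = counts / total
    rng = np.random.default_rng(seed)
    draws = np.empty((reps, len(counts)))
    for r in range(reps):  # sequential draws keep replicate streams nested
        draws[r] = rng.multinomial(draw_n, probs.to_numpy())
    simulated = draws / draw_n
    if percentiles is None:
        lo, hi = simulated.min(axis=0), simulated.max(axis=0)
    else:
        lo = np.percentile(simulated, percentiles[0], axis=0)
        hi = np.percentile(simulated, percentiles[1], axis=0)
    envelope = pd.DataFrame({"min": lo, "max": hi}, index=counts.index)
    return CompositionEnvelope(
        species_probabilities=probs,
        draw_n=draw_n,
        reps=reps,
        envelope=envelope,
        seed=seed,
        simulated=simulated,
    )


def classify_subzones(
    occurrences: OccurrenceTable, envelope: CompositionEnvelope
) -> pd.DataFrame:
    """Flag, per subzone and species, whether the observed relative
    abundance falls strictly outside the bootstrap envelope.

    Returns a tidy frame (subzone, species, observed, env_min, env_max,
    outside, evaluable); a subzone counts as deviating when any of its
    species is outside.  Empty subzones are reported as not evaluable.
    """
    missing = [s for s in occurrences.species if s not in envelope.envelope.index]
    if missing:
        raise ValueError(f"species missing from envelope: {missing}")
    rel = occurrences.relative_abundances()
    rows = []
    for subzone in occurrences.subzones:
        evaluable = occurrences.subzone_totals()[subzone] > 0
        for species in occurrences.species:
            obs = rel.at[subzone, species] if evaluable else np.nan
            lo = envelope.envelope.at[species, "min"]
            hi = envelope.envelope.at[species, "max"]
            outside = bool(evaluable and (obs < lo or obs > hi))
            rows.append((subzone, species, obs, lo, hi, outside, bool(evaluable)))
    frame = pd.DataFrame(
        rows,
        columns=["subzone", "species", "observed", "env_min", "env_max", "outside", "evaluable"],
    )
    frame.attrs["subzone_flags"] = {
        sz: bool(frame.loc[(frame.subzone == sz) & frame.evaluable, "outside"].any())
        for sz in occurrences.subzones
    }
    return frame
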