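"""Event-driven two-helicase race on a linear duplex.

One enzyme enters at a blunt end and unwinds with two motors of unequal
speed: the slower motor (RecB, velocity v_B) tracks the 3'-ended strand, the
faster one (RecD, v_D) the 5'-ended strand, so a single-stranded loop of
size (v_D − v_B)·t accumulates between them.  Two events can trigger the
nuclease:

* **Chi** — the slower motor traverses a correctly oriented Chi site
  (5'-GCTGGTGG-3') at time t_chi = d_chi/v_B; the nuclease swings fast
  (~1 ms) and the cut lands essentially at the Chi-proximal position.
* **End stop** — the fast motor reaches the far end at t_end = S/v_D; a
  sensitized enzyme (probability p_sens = [I]/([I]+k_sens)) then cuts where
  the slow motor is after a slow swing (~200–300 ms), i.e. at
  S·(v_B/v_D) + v_B·delay.

Whichever armed trigger fires first wins; an unsensitized enzyme that has
no Chi (or loses Chi recognition) releases a full-length unwound strand.
Cut positions are distances from the entry end; the labeled fragment is the
complement S − position.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Union

import numpy as np

from .kinetics import motor_velocity, velocity_ratio
from .params import (
    EntryEnd,
    EnzymeParams,
    InvalidParameterError,
    ReactionConditions,
    SubstrateSpec,
)

CHI_MOTIF = "GCTGGTGG"

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class SequenceError(ValueError):
    """A DNA sequence contains characters outside {A, C, G, T}."""


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def chi_scan(
    sequence: str, entry_end: EntryEnd, chi_offset_nt: int = 5
) -> List[int]:
    """Scan a duplex for active Chi sites and return cut distances from entry.

    ``sequence`` is the top strand written 5'→3'.  Chi is only recognized
    when the octamer is read 3'-ended from the chosen entry: the top strand
    for right entry, the bottom-strand complement for left entry — entering
    from the wrong end makes the same physical site invisible.  Each hit is
    converted to a nominal cut distance: distance from entry to the motif
    base nearest the entry, minus ``chi_offset_nt`` (the cut sits a few nt
    3' of the octamer, on the entry side); distances that would fall before
    the entry are clamped to 0.  Returned sorted ascending.
    """
    seq = sequence.upper()
    if any(c not in "ACGT" for c in seq):
        bad = sorted({c for c in seq if c not in "ACGT"})
        raise SequenceError(f"non-DNA characters in sequence: {bad}")
    if len(seq) < len(CHI_MOTIF):
        raise SequenceError("sequence shorter than the Chi octamer")
    if entry_end not in ("left", "right"):
        raise InvalidParameterError(f"bad entry_end {entry_end!r}")
    # Entering from the left of the duplex is the same geometry as entering
    # from the right of the reverse complement.
    strand = seq if entry_end == "right" else _revcomp(seq)
    n = len(strand)
    cuts = []
    start = 0
    while True:
        i = strand.find(CHI_MOTIF, start)
        if i < 0:
            break
        nearest_entry_index = i + len(CHI_MOTIF) - 1
        dist = (n - 1) - nearest_entry_index
        cuts.append(max(0, dist - chi_offset_nt))
        start = i + 1
    return sorted(cuts)


def predicted_cut_position(
    S: float, r: float, advance_nt: float
) -> Optional[float]:
    """Closed-form end-stop cut position S·r + advance, or None if it would
    land at or beyond the far end (the slow motor finishes before the
    nuclease lands, so no internal cut is made)."""
    if S <= 0:
        raise InvalidParameterError("S must be > 0")
    if not 0 < r <= 1:
        raise InvalidParameterError("r must be in (0, 1]")
    if advance_nt < 0:
        raise InvalidParameterError("advance_nt must be >= 0")
    pos = S * r + advance_nt
    return pos if pos < S else None


def end_stop_probability(inhibitor_uM: float, k_sens_uM: float) -> float:
    """Hyperbolic sensitization occupancy p_sens = [I]/([I] + k_sens)."""
    if inhibitor_uM < 0 or k_sens_uM <= 0:
        raise InvalidParameterError("bad sensitization parameters")
    if inhibitor_uM == 0:
        return 0.0
    return inhibitor_uM / (inhibitor_uM + k_sens_uM)


@dataclass(frozen=True)
class CutEvent:
    """Outcome of one unwinding trajectory."""

    trigger: str  # "chi" | "end_stop" | "none"
    position_nt: Optional[float] = None
    time_ms: Optional[float] = None

    def __post_init__(self) -> None:
        if self.trigger not in ("chi", "end_stop", "none"):
            raise InvalidParameterError(f"bad trigger {self.trigger!r}")
        if self.trigger == "none" and self.position_nt is not None:
            raise InvalidParameterError("trigger 'none' carries no position")


def _gamma_delay(rng: np.random.Generator, mean: float, cv: float) -> float:
    """Gamma-distributed delay with the given mean and coefficient of
    variation; degenerate (exact mean) at cv = 0 or mean = 0."""
    if mean == 0 or cv == 0:
        return mean
    shape = 1.0 / cv**2
    return float(rng.gamma(shape, mean * cv**2))


def _velocities(enz: EnzymeParams, cond: ReactionConditions) -> tuple[float, float]:
    """(v_B, v_D) in nt/ms.  Table mode adopts the v_D = 1 nt/ms convention
    so times in ms equal RecD distances in nt."""
    r = velocity_ratio(enz, cond)
    if cond.mode == "table":
        v_d = 1.0
    else:
        v_d = motor_velocity(enz.recD, cond)
        if v_d <= 0:
            raise InvalidParameterError("degenerate RecD velocity")
    return r * v_d, v_d


def simulate_molecule(
    sub: SubstrateSpec,
    enz: EnzymeParams,
    cond: ReactionConditions,
    rng: np.random.Generator,
) -> CutEvent:
    """Simulate one molecule and return its cut event.

    Chi wins the race when the slow motor reaches the Chi cut site before
    the fast motor reaches the far end (t_chi < t_end) and the site is
    recognized (Bernoulli ``p_chi_recognition``); the cut is pinned at the
    scanned Chi position with ±1 nt jitter after a fast swing.  Otherwise a
    sensitized enzyme (Bernoulli p_sens) cuts at the slow motor's position
    after a slow Gamma-distributed swing; if that position reaches the far
    end, or the enzyme is unsensitized, no internal cut is made.
    """
    S = float(sub.length_nt)
    v_b, v_d = _velocities(enz, cond)
    r = v_b / v_d
    t_end = S / v_d

    chi_dist = sub.chi_cut_from_entry
    chi_recognized = (
        chi_dist is not None and rng.random() < enz.p_chi_recognition
    )
    if chi_recognized:
        t_chi = chi_dist / v_b
        if t_chi < t_end:
            jitter = int(rng.integers(-1, 2))  # uniform over a 3-nt window
            pos = min(S, max(0.0, float(chi_dist + jitter)))
            delay = _gamma_delay(rng, enz.swing.tau_chi_ms, enz.swing.cv)
            return CutEvent("chi", pos, t_chi + delay)

    p_sens = end_stop_probability(cond.inhibitor_uM, enz.k_sens_uM)
    if p_sens > 0 and rng.random() < p_sens:
        if cond.mode == "table":
            mean_adv = enz.calibration.lookup(cond.inhibitor_uM).advance_nt
            advance = _gamma_delay(rng, mean_adv, enz.swing.cv)
        else:
            delay = _gamma_delay(rng, enz.swing.tau_stop_ms, enz.swing.cv)
            advance = v_b * delay
        pos = S * r + advance
        if pos < S:
            return CutEvent("end_stop", pos, t_end + advance / v_b)
    return CutEvent("none")


@dataclass(frozen=True)
class FragmentRecord:
    """Count of labeled fragments of one length produced by one trigger."""

    length_nt: int
    count: int
    trigger: str


@dataclass(frozen=True)
class FragmentSet:
    """Population of labeled single-stranded fragment lengths for one lane."""

    substrate: SubstrateSpec
    inhibitor_uM: float
    records: tuple[FragmentRecord, ...]
    n_molecules: int
    full_length_count: int

    def __post_init__(self) -> None:
        total = sum(rec.count for rec in self.records) + self.full_length_count
        if total != self.n_molecules:
            raise InvalidParameterError(
                f"fragment counts ({total}) do not sum to n_molecules "
                f"({self.n_molecules})"
            )
        for rec in self.records:
            if not 0 < rec.length_nt <= self.substrate.length_nt:
                raise InvalidParameterError(
                    f"fragment length {rec.length_nt} outside "
                    f"(0, {self.substrate.length_nt}]"
                )

    @property
    def fragments(self) -> list[tuple[int, int]]:
        """(length_nt, count) pairs aggregated over triggers, sorted."""
        agg: Counter = Counter()
        for rec in self.records:
            agg[rec.length_nt] += rec.count
        return sorted(agg.items())

    def mean_length(self, trigger: Optional[str] = None) -> float:
        recs = [r for r in self.records if trigger is None or r.trigger == trigger]
        n = sum(r.count for r in recs)
        if n == 0:
            raise InvalidParameterError("no fragments match the trigger")
        return sum(r.length_nt * r.count for r in recs) / n


def simulate_population(
    n: int,
    sub: SubstrateSpec,
    enz: EnzymeParams,
    cond: ReactionConditions,
    seed: Union[int, np.random.Generator, np.random.SeedSequence],
) -> FragmentSet:
    """Simulate ``n`` molecules and aggregate labeled fragment lengths.

    Labeled fragment length is S − cut position, rounded to the nearest
    nucleotide; uncut molecules count as full length.  Deterministic for a
    fixed seed.
    """
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    S = sub.length_nt
    counts: Counter = Counter()
    full = 0
    for _ in range(n):
        ev = simulate_molecule(sub, enz, cond, rng)
        if ev.trigger == "none":
            full += 1
        else:
            length = int(round(S - ev.position_nt))
            length = min(max(length, 1), S)
            counts[(length, ev.trigger)] += 1
    records = tuple(
        FragmentRecord(length, cnt, trig)
        for (length, trig), cnt in sorted(counts.items())
    )
    return FragmentSet(
        substrate=sub,
        inhibitor_uM=cond.inhibitor_uM,
        records=records,
        n_molecules=n,
        full_length_count=full,
    )


def loop_size(enz: EnzymeParams, cond: ReactionConditions, t_ms: float) -> float:
    """Single-stranded loop accumulated between the motors by time t:
    (v_D − v_B)·t, zero iff the motors run at the same speed."""
    if t_ms < 0:
        raise InvalidParameterError("t_ms must be >= 0")
    v_b, v_d = _velocities(enz, cond)
    size = (v_d - v_b) * t_ms
    if size < 0:
        raise InvalidParameterError("negative loop: RecB faster than RecD")
    return size
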