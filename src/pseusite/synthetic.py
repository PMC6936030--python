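"""Seeded synthetic fragment datasets with planted positional signal.

The generator emulates the structure of the public Ψ benchmark sets:
balanced positive/negative collections of odd-length U-centered
fragments over {A,C,G,U}.  The negative class is drawn from a
background composition at every position (uniform by default, matching
the null hypothesis that the four nucleotides appear at random); the
positive class uses the same background except at explicitly biased
positions, where a chosen nucleotide is over- or under-represented.
This mimics the position-specific enrichment seen around genuine Ψ
sites — e.g. guanine enrichment just 3' of the central uridine — while
keeping the true signal known, so encoder/classifier/logo stages can be
tested for signal recovery and for calibration under the null.

Defaults mirror the H. sapiens development set shape: 21-nt fragments,
495 positives and 495 negatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .sequence_io import FragmentDataset, UCenteredFragment

NUCLEOTIDES = ("A", "C", "G", "U")

UNIFORM_BACKGROUND: Mapping[str, float] = {n: 0.25 for n in NUCLEOTIDES}


class SignalSpecError(ValueError):
    """Raised for inconsistent simulation specifications."""


@dataclass(frozen=True)
class SignalSpec:
    """Specification of a synthetic fragment dataset.

    ``biases`` is a collection of ``(position, nucleotide, probability)``
    triples applying to the positive class only; positions are 0-based
    fragment-internal indices.  At a biased position the named
    nucleotides take their stated probabilities and the remaining mass
    is shared among the unnamed nucleotides in proportion to the
    background.  The central position is forced to U in both classes.
    """

    window_length: int = 21
    n_positive: int = 495
    n_negative: int = 495
    biases: tuple[tuple[int, str, float], ...] = ()
    background: Mapping[str, float] = field(
        default_factory=lambda: dict(UNIFORM_BACKGROUND)
    )
    seed: int = 0
    shuffle: bool = False

    @property
    def center_index(self) -> int:
        return (self.window_length - 1) // 2

    def validate(self) -> None:
        if self.window_length < 3 or self.window_length % 2 == 0:
            raise SignalSpecError(
                f"window_length must be odd and >= 3, got {self.window_length}"
            )
        if self.n_positive < 0 or self.n_negative < 0:
            raise SignalSpecError("sample counts must be non-negative")
        if set(self.background) != set(NUCLEOTIDES):
            raise SignalSpecError("background must assign a probability to each of A,C,G,U")
        bg = np.array([self.background[n] for n in NUCLEOTIDES], dtype=float)
        if (bg < 0).any() or not np.isclose(bg.sum(), 1.0):
            raise SignalSpecError("background probabilities must be >= 0 and sum to 1")
        per_position: dict[int, float] = {}
        for pos, nuc, prob in self.biases:
            if not 0 <= pos < self.window_length:
                raise SignalSpecError(f"bias position {pos} outside fragment")
            if nuc not in NUCLEOTIDES:
                raise SignalSpecError(f"bias nucleotide {nuc!r} not one of A,C,G,U")
            if not 0.0 <= prob <= 1.0:
                raise SignalSpecError(f"bias probability {prob} outside [0, 1]")
            if pos == self.center_index and nuc != "U":
                raise SignalSpecError(
                    "the central position is always U; a bias there for "
                    f"{nuc!r} is contradictory"
                )
            per_position[pos] = per_position.get(pos, 0.0) + prob
        for pos, total in per_position.items():
            if total > 1.0 + 1e-9:
                raise SignalSpecError(
                    f"bias probabilities at position {pos} sum to {total} > 1"
                )


def _position_probabilities(spec: SignalSpec, positive: bool) -> np.ndarray:
    """(window_length, 4) matrix of per-position nucleotide probabilities."""
    bg = np.array([spec.background[n] for n in NUCLEOTIDES], dtype=float)
    probs = np.tile(bg, (spec.window_length, 1))
    if positive:
        biased: dict[int, dict[str, float]] = {}
        for pos, nuc, prob in spec.biases:
            biased.setdefault(pos, {})[nuc] = prob
        for pos, assignment in biased.items():
            row = np.zeros(4)
            free = np.ones(4, dtype=bool)
            for nuc, prob in assignment.items():
                j = NUCLEOTIDES.index(nuc)
                row[j] = prob
                free[j] = False
            remainder = 1.0 - row.sum()
            if free.any():
                weights = bg[free]
                if weights.sum() > 0:
                    row[free] = remainder * weights / weights.sum()
                else:
                    row[free] = remainder / free.sum()
            probs[pos] = row
    # Central position is U with probability 1 in both classes.
    probs[spec.center_index] = [0.0, 0.0, 0.0, 1.0]
    return probs


def _draw_class(
    rng: np.random.Generator, probs: np.ndarray, n: int
) -> list[str]:
    if n == 0:
        return []
    window = probs.shape[0]
    columns = np.empty((n, window), dtype="<U1")
    for pos in range(window):
        columns[:, pos] = rng.choice(NUCLEOTIDES, size=n, p=probs[pos])
    return ["".join(row) for row in columns]


def simulate_dataset(spec: SignalSpec) -> FragmentDataset:
    """Draw a labeled :class:`FragmentDataset` from ``spec``.

    Deterministic for a fixed spec: one NumPy generator seeded with
    ``spec.seed`` drives all draws.  Fragments are emitted positives
    first, then negatives, then shuffled with the same stream when
    ``spec.shuffle`` is set.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    pos_probs = _position_probabilities(spec, positive=True)
    neg_probs = _position_probabilities(spec, positive=False)
    center = spec.center_index + 1  # 1-based position of the central U

    fragments = [
        UCenteredFragment(residues=s, label=1, origin=(f"sim_pos_{i:05d}", center))
        for i, s in enumerate(_draw_class(rng, pos_probs, spec.n_positive))
    ] + [
        UCenteredFragment(residues=s, label=0, origin=(f"sim_neg_{i:05d}", center))
        for i, s in enumerate(_draw_class(rng, neg_probs, spec.n_negative))
    ]
    if spec.shuffle:
        order = rng.permutation(len(fragments))
        fragments = [fragments[i] for i in order]
    return FragmentDataset(fragments=fragments, species_tag="custom")
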