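"""Synthetic labeled protein datasets with planted composition differences.

Sequences are drawn i.i.d. residue-by-residue from a class-specific emission
distribution over the 20 canonical residues.  The positive class shifts an
extra probability mass ``delta`` onto the residues of one reduced-alphabet
group (proportionally within the group, renormalizing the rest), so the two
classes differ only in single-residue composition — exactly the signal the
k=1 reduced-alphabet features are designed to detect.  ``delta = 0`` is the
exact null: both classes share one distribution.

Lengths follow a log-normal law (median 400, sigma 0.55 by default) floored
at 50 residues and capped at 5000, mimicking curated TF collections where
sequences are at least 50 residues and ~90% fall under 1000.

i.i.d. emission carries no positional structure, so k >= 2 features contain
no extra signal beyond composition; a Markov emitter is the natural
extension point for planting higher-order signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from methylpref.io import LabeledDataset, ProteinRecord
from methylpref.raac import OP11, ReductionScheme, load_scheme

# Background residue frequencies (approximate vertebrate proteome composition).
BACKGROUND_FREQUENCIES = {
    "A": 0.070, "C": 0.023, "D": 0.047, "E": 0.071, "F": 0.037,
    "G": 0.066, "H": 0.026, "I": 0.043, "K": 0.057, "L": 0.100,
    "M": 0.021, "N": 0.036, "P": 0.063, "Q": 0.048, "R": 0.057,
    "S": 0.083, "T": 0.053, "V": 0.060, "W": 0.012, "Y": 0.027,
}


class SpecError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a two-class synthetic protein dataset.

    delta is the excess probability mass planted on ``effect_group`` (an
    Op-scheme group symbol) in the positive class; 0 gives the exact null.
    """

    n_pos: int = 270
    n_neg: int = 106
    effect_group: str = "E"
    delta: float = 0.0
    scheme: str = "Op11"
    length_median: float = 400.0
    length_sigma: float = 0.55
    min_length: int = 50
    max_length: int = 5000
    seed: int = 0

    def __post_init__(self):
        if self.n_pos <= 0 or self.n_neg <= 0:
            raise SpecError(
                f"class sizes must be positive (n_pos={self.n_pos}, n_neg={self.n_neg})"
            )
        if not (0 <= self.delta < 1):
            raise SpecError(f"delta must be in [0, 1), got {self.delta}")
        if self.min_length < 1 or self.max_length < self.min_length:
            raise SpecError("invalid length bounds")
        scheme = load_scheme(self.scheme)
        if self.effect_group not in scheme.symbols:
            raise SpecError(
                f"effect_group {self.effect_group!r} not a symbol of {scheme.name}"
            )

    def emission_distributions(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """(positive, negative) residue distributions and the residue order.

        The negative class uses the background; the positive class scales the
        effect group's residues so their total mass rises by delta, and the
        remaining residues so total mass stays 1.
        """
        scheme = load_scheme(self.scheme)
        residues = sorted(BACKGROUND_FREQUENCIES)
        base = np.array([BACKGROUND_FREQUENCIES[r] for r in residues])
        base = base / base.sum()
        members = dict(scheme.groups)[self.effect_group]
        in_group = np.array([r in members for r in residues])
        m = base[in_group].sum()
        if m + self.delta >= 1.0:
            raise SpecError(
                f"delta={self.delta} pushes group {self.effect_group!r} mass "
                f"({m:.3f}) past 1"
            )
        pos = base.copy()
        pos[in_group] *= (m + self.delta) / m
        pos[~in_group] *= (1.0 - m - self.delta) / (1.0 - m)
        return pos, base, residues


def _draw_lengths(rng: np.random.Generator, n: int, spec: SyntheticSpec) -> np.ndarray:
    mu = np.log(spec.length_median)
    lengths = rng.lognormal(mean=mu, sigma=spec.length_sigma, size=n)
    return np.clip(np.round(lengths), spec.min_length, spec.max_length).astype(int)


def generate(spec: SyntheticSpec) -> LabeledDataset:
    """Generate a labeled dataset; byte-identical FASTA given the same spec."""
    rng = np.random.default_rng(spec.seed)
    p_pos, p_neg, residues = spec.emission_distributions()
    residues = np.array(residues)

    def make(n: int, probs: np.ndarray, prefix: str) -> list[ProteinRecord]:
        lengths = _draw_lengths(rng, n, spec)
        recs = []
        width = max(4, len(str(n)))
        for i, L in enumerate(lengths):
            seq = "".join(rng.choice(residues, size=L, p=probs))
            recs.append(ProteinRecord(id=f"{prefix}_{i + 1:0{width}d}", sequence=seq))
        return recs

    pos = make(spec.n_pos, p_pos, "pos")
    neg = make(spec.n_neg, p_neg, "neg")
    labels = np.concatenate([np.ones(spec.n_pos, int), np.zeros(spec.n_neg, int)])
    return LabeledDataset(records=pos + neg, labels=labels)


def worked_example_fixtures() -> dict:
    """Small fixed sequences with hand-computed expected encodings.

    Used by regression tests: the six-residue example with its 3-mer windows
    and its 11-group reduction, plus the full canonical alphabet and its
    image (exactly 11 distinct symbols under Op11).
    """
    full = "ACDEFGHIKLMNPQRSTVWY"
    return {
        "sequence": "ACDEFG",
        "kmers_k3": ["ACD", "CDE", "DEF", "EFG"],
        "op11_reduction": "AVNEFG",
        "full_alphabet": full,
        "full_alphabet_op11_symbols": set("GIFALEPNHTV"),
    }
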