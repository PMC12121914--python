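"""Reduced amino-acid alphabet (RAAC) encoding and k-mer frequency features.

A reduction scheme partitions the 20 canonical residues into ``op`` groups,
each carrying a single-character symbol; a protein is rewritten residue-wise
over the symbol alphabet and then encoded as the relative frequencies of all
``op**k`` overlapping k-mers (sliding window, step 1).

The canonical 11-group scheme (``Op11``) groups residues by structural
similarity derived from protein-block clustering:

====== =========================
symbol members
====== =========================
G      G
I      I, V
F      F, Y, W
A      A
L      L, M
E      E, Q, R, K
P      P
N      N, D
H      H, S
T      T
V      C
====== =========================

Note the symbol assignments: cysteine's group carries symbol ``V`` while the
{I, V} group carries symbol ``I``.  Schemes for other group counts
(5, 8, 9, 13) ship as plain-text scheme files; ``Op20`` is the identity
(no reduction), under which k=1 features equal classical amino-acid
composition.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from methylpref.io import CANONICAL_RESIDUES, ProteinRecord

logger = logging.getLogger(__name__)


class SchemeError(ValueError):
    """Raised when a reduction scheme is not a partition of the 20 residues."""


class EncodingError(ValueError):
    """Raised when a sequence cannot be reduced or featurized."""


@dataclass(frozen=True)
class ReductionScheme:
    """A named partition of the 20 canonical residues into symbol groups.

    ``groups`` is an ordered tuple of ``(symbol, members)`` pairs; the
    declared order fixes the lexicographic k-mer ordering used by
    :func:`featurize`, so feature matrices are reproducible bit-for-bit.
    """

    name: str
    groups: tuple[tuple[str, str], ...]

    def __post_init__(self):
        seen: set[str] = set()
        symbols = [s for s, _ in self.groups]
        if len(set(symbols)) != len(symbols):
            raise SchemeError(f"{self.name}: duplicate group symbols {symbols}")
        for symbol, members in self.groups:
            if len(symbol) != 1:
                raise SchemeError(f"{self.name}: symbol {symbol!r} must be one character")
            if not members:
                raise SchemeError(f"{self.name}: group {symbol!r} is empty")
            for res in members:
                if res not in CANONICAL_RESIDUES:
                    raise SchemeError(f"{self.name}: {res!r} is not a canonical residue")
                if res in seen:
                    raise SchemeError(f"{self.name}: residue {res!r} assigned twice")
                seen.add(res)
        missing = CANONICAL_RESIDUES - seen
        if missing:
            raise SchemeError(f"{self.name}: residues not assigned: {sorted(missing)}")

    @property
    def size(self) -> int:
        """Number of groups (the scheme's ``op``)."""
        return len(self.groups)

    @property
    def symbols(self) -> str:
        return "".join(s for s, _ in self.groups)

    def mapping(self) -> dict[str, str]:
        """Residue -> group-symbol map."""
        return {res: sym for sym, members in self.groups for res in members}


@dataclass(frozen=True)
class ReducedSequence:
    """A protein rewritten over a scheme's symbol alphabet (length preserved)."""

    source_id: str
    symbols: str
    scheme_name: str


@dataclass(frozen=True)
class KmerFeatureVector:
    """Relative k-mer frequencies over a scheme's symbols, fixed ordering.

    ``values`` has length ``size**k``; entries sum to 1 whenever the sequence
    admits at least one window (``n_windows = L - k + 1 > 0``).
    """

    values: np.ndarray
    k: int
    scheme_name: str
    n_windows: int


# Canonical 11-group protein-block clustering scheme.
OP11 = ReductionScheme(
    name="Op11",
    groups=(
        ("G", "G"),
        ("I", "IV"),
        ("F", "FYW"),
        ("A", "A"),
        ("L", "LM"),
        ("E", "EQRK"),
        ("P", "P"),
        ("N", "ND"),
        ("H", "HS"),
        ("T", "T"),
        ("V", "C"),
    ),
)

# Identity scheme: every residue its own group (alphabetical order).
OP20 = ReductionScheme(
    name="Op20",
    groups=tuple((r, r) for r in sorted(CANONICAL_RESIDUES)),
)

_BUNDLED_FILES = {"Op5": "op5.txt", "Op8": "op8.txt", "Op9": "op9.txt", "Op13": "op13.txt"}
_BUILTIN = {"Op11": OP11, "Op20": OP20}


def parse_scheme_text(name: str, text: str) -> ReductionScheme:
    """Parse the plain-text scheme format: one ``SYMBOL: RESIDUES`` line per group."""
    groups = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise SchemeError(f"{name}: malformed scheme line {line!r}")
        symbol, members = line.split(":", 1)
        groups.append((symbol.strip(), members.strip().replace(" ", "")))
    return ReductionScheme(name=name, groups=tuple(groups))


def load_scheme(name_or_path: str | Path | ReductionScheme) -> ReductionScheme:
    """Resolve a scheme by registered name (``Op5``..``Op20``) or file path."""
    if isinstance(name_or_path, ReductionScheme):
        return name_or_path
    key = str(name_or_path)
    if key in _BUILTIN:
        return _BUILTIN[key]
    if key in _BUNDLED_FILES:
        text = (
            resources.files("methylpref") / "schemes" / _BUNDLED_FILES[key]
        ).read_text()
        return parse_scheme_text(key, text)
    path = Path(key)
    if path.exists():
        return parse_scheme_text(path.stem, path.read_text())
    raise SchemeError(
        f"unknown scheme {key!r}; registered: {sorted(registered_schemes())}"
    )


def registered_schemes() -> list[str]:
    return sorted(_BUILTIN) + sorted(_BUNDLED_FILES)


def scheme_for_op(op: int) -> ReductionScheme:
    """Resolve a scheme by its group count (5, 8, 9, 11, 13 or 20)."""
    return load_scheme(f"Op{op}")


def reduce_sequence(record: ProteinRecord, scheme: ReductionScheme) -> ReducedSequence:
    """Replace each residue by its group symbol; length is preserved."""
    mapping = scheme.mapping()
    out = []
    for i, res in enumerate(record.sequence):
        try:
            out.append(mapping[res])
        except KeyError:
            raise EncodingError(
                f"record {record.id!r}: residue {res!r} at position {i + 1} "
                f"is not covered by scheme {scheme.name}"
            ) from None
    return ReducedSequence(source_id=record.id, symbols="".join(out), scheme_name=scheme.name)


def extract_kmers(reduced: ReducedSequence | str, k: int) -> list[str]:
    """All ``L - k + 1`` overlapping windows in order; empty list when L < k."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    s = reduced.symbols if isinstance(reduced, ReducedSequence) else reduced
    if len(s) < k:
        logger.warning("sequence of length %d shorter than k=%d; no windows", len(s), k)
        return []
    return [s[i : i + k] for i in range(len(s) - k + 1)]


def kmer_labels(scheme: ReductionScheme, k: int) -> list[str]:
    """All ``size**k`` k-mers in lexicographic order over the scheme's symbol order."""
    return ["".join(p) for p in itertools.product(scheme.symbols, repeat=k)]


def featurize(
    reduced: ReducedSequence,
    scheme: ReductionScheme,
    k: int,
    lenient: bool = False,
) -> KmerFeatureVector:
    """Encode a reduced sequence as a relative-frequency vector over all k-mers.

    The k-mer -> index map is lexicographic over the scheme's declared symbol
    order and identical across sequences.  Sequences shorter than k raise
    :class:`EncodingError` unless ``lenient=True``, in which case a zero
    vector (``n_windows=0``) is returned with a warning so one short protein
    cannot abort a batch screen.
    """
    size = scheme.size
    index = {sym: i for i, sym in enumerate(scheme.symbols)}
    L = len(reduced.symbols)
    n_windows = L - k + 1
    values = np.zeros(size**k, dtype=float)
    if n_windows <= 0:
        if not lenient:
            raise EncodingError(
                f"record {reduced.source_id!r}: length {L} < k={k}; "
                "cannot featurize in strict mode"
            )
        logger.warning(
            "record %s: length %d < k=%d; zero feature vector", reduced.source_id, L, k
        )
        return KmerFeatureVector(values=values, k=k, scheme_name=scheme.name, n_windows=0)
    try:
        # index of window = base-`size` integer over symbol ranks
        for i in range(n_windows):
            idx = 0
            for ch in reduced.symbols[i : i + k]:
                idx = idx * size + index[ch]
            values[idx] += 1.0
    except KeyError as exc:
        raise EncodingError(
            f"record {reduced.source_id!r}: symbol {exc.args[0]!r} not in scheme "
            f"{scheme.name}"
        ) from None
    values /= n_windows
    return KmerFeatureVector(values=values, k=k, scheme_name=scheme.name, n_windows=n_windows)


def feature_matrix(
    records: list[ProteinRecord],
    scheme: ReductionScheme,
    k: int,
    lenient: bool = False,
) -> np.ndarray:
    """Stack per-record feature vectors into an ``(n, size**k)`` matrix."""
    rows = [
        featurize(reduce_sequence(r, scheme), scheme, k, lenient=lenient).values
        for r in records
    ]
    if not rows:
        return np.zeros((0, scheme.size**k))
    return np.vstack(rows)
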