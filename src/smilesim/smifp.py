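"""SMILES fingerprints (SMIfp): symbol-frequency vectors.

A SMIfp represents a SMILES string as a fixed-dimension vector of
symbol occurrence counts.  The classic fingerprint uses 34 symbols; the
extended 38D variant drops the rare '%' and adds the chirality tokens
'@' and '@@', the dot disconnection '.', and the directional bonds '/'
and '\\', which are frequent in drug-like SMILES.  Fingerprints are
computed on the raw SMILES (before two-character-atom collapsing) so
that these tokens survive; two-character symbols are matched greedily,
so '@@' consumes both characters and never counts as two '@'.

Distances/similarities: City Block (Manhattan) distance, a monotone
``1/(1+CBD)`` similarity transform of it, and the count Tanimoto
coefficient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .prep import CompoundRecord

logger = logging.getLogger(__name__)

# 15 atoms, 2 bonds, branches, brackets, charges, H, ring digits, '%'
_SMIFP34_SYMBOLS = (
    "C c N n O o S s P p F I Cl Br B = # ( ) [ ] + - H 1 2 3 4 5 6 7 8 9 %".split()
)
_SMIFP38_SYMBOLS = [s for s in _SMIFP34_SYMBOLS if s != "%"] + ["@", "@@", ".", "\\", "/"]


@dataclass(frozen=True)
class FingerprintAlphabet:
    """Ordered symbol list defining the fingerprint dimensions."""

    name: str
    symbols: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be unique")
        if any(len(s) not in (1, 2) for s in self.symbols):
            raise ValueError("alphabet symbols must be one or two characters")


def smifp34() -> FingerprintAlphabet:
    """The 34-symbol fingerprint alphabet."""
    return FingerprintAlphabet("smifp34", tuple(_SMIFP34_SYMBOLS))


def smifp38() -> FingerprintAlphabet:
    """The extended 38-symbol alphabet: drop '%', add @ @@ . \\ /."""
    return FingerprintAlphabet("smifp38", tuple(_SMIFP38_SYMBOLS))


def load_alphabet(path: str | Path, name: str | None = None) -> FingerprintAlphabet:
    """Read an alphabet config file: one symbol per line, '#' comments."""
    symbols = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            symbols.append(line)
    return FingerprintAlphabet(name or Path(path).stem, tuple(symbols))


def get_alphabet(spec: str) -> FingerprintAlphabet:
    """Resolve 'smifp34', 'smifp38', or a config-file path."""
    if spec == "smifp34":
        return smifp34()
    if spec == "smifp38":
        return smifp38()
    return load_alphabet(spec)


@dataclass
class Fingerprint:
    """Per-symbol occurrence counts of one SMILES string."""

    alphabet: FingerprintAlphabet
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.alphabet.symbols),):
            raise ValueError("count vector length must match the alphabet size")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")


def compute_fingerprint(
    record: CompoundRecord | str, alphabet: FingerprintAlphabet
) -> Fingerprint:
    """Tokenize the raw SMILES greedily and count alphabet symbols.

    Characters outside the alphabet are skipped (tallied in a debug log
    line).  Two-character symbols are matched before their one-character
    prefixes.
    """
    s = record.raw_smiles if isinstance(record, CompoundRecord) else record
    s = "".join(s.split())
    index = {sym: i for i, sym in enumerate(alphabet.symbols)}
    two_char = {sym for sym in alphabet.symbols if len(sym) == 2}
    counts = np.zeros(len(alphabet.symbols), dtype=np.int64)
    unknown = 0
    i = 0
    while i < len(s):
        pair = s[i : i + 2]
        if pair in two_char:
            counts[index[pair]] += 1
            i += 2
        elif s[i] in index:
            counts[index[s[i]]] += 1
            i += 1
        else:
            unknown += 1
            i += 1
    if unknown:
        logger.debug("fingerprint skipped %d characters outside alphabet %s", unknown, alphabet.name)
    return Fingerprint(alphabet, counts)


def _check_same_alphabet(f1: Fingerprint, f2: Fingerprint) -> None:
    if f1.alphabet.symbols != f2.alphabet.symbols:
        raise ValueError(
            f"alphabet mismatch: {f1.alphabet.name} vs {f2.alphabet.name}"
        )


def city_block_distance(f1: Fingerprint, f2: Fingerprint) -> int:
    """Manhattan distance between count vectors."""
    _check_same_alphabet(f1, f2)
    return int(np.abs(f1.counts - f2.counts).sum())


def cbd_similarity(f1: Fingerprint, f2: Fingerprint) -> float:
    """Monotone similarity transform ``1/(1 + CBD)`` in (0, 1].

    The transform only rescales the distance, so AUC-based rankings are
    unaffected by its particular shape.
    """
    return 1.0 / (1.0 + city_block_distance(f1, f2))


def tanimoto_counts(f1: Fingerprint, f2: Fingerprint) -> float:
    """Count Tanimoto: ``a.b / (|a|^2 + |b|^2 - a.b)``."""
    _check_same_alphabet(f1, f2)
    a = f1.counts.astype(np.float64)
    b = f2.counts.astype(np.float64)
    dot = float(a @ b)
    denom = float(a @ a) + float(b @ b) - dot
    if denom == 0.0:
        logger.warning("tanimoto_counts of two all-zero fingerprints; returning 0")
        return 0.0
    return dot / denom
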