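"""SMILES preprocessing for string-based similarity kernels.

Every kernel in this package compares SMILES strings character by
character, so atoms written with two characters ('Cl', 'Br', ...) are
first collapsed to single placeholder characters.  The LINGO family of
kernels additionally requires all ring-closure digits to be set to '0'
so that the same ring pattern yields the same q-grams regardless of
ring numbering.

Input SMILES are assumed to be canonical/unique already (as produced by
a cheminformatics toolkit); no canonicalization is performed here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

#: Default two-character-atom collapsing table.  Values are single
#: characters that do not collide with SMILES organic-subset symbols.
DEFAULT_ATOM_TABLE: dict[str, str] = {
    "Cl": "L",
    "Br": "R",
    "Si": "A",
    "Se": "Z",
}

#: Single-character symbols already meaningful in SMILES; replacement
#: values must not collide with these.
_RESERVED_SINGLE_CHARS = set("BCNOPSFIHbcnops") | set("=#-+()[]@/\\.%0123456789")


def normalize_atoms(raw: str, table: Mapping[str, str] | None = None) -> str:
    """Collapse two-character atom tokens to single characters.

    Table keys are matched greedily left to right; all other characters
    pass through unchanged.  Whitespace is stripped first (spaces are
    not legal SMILES tokens).  Idempotent for collision-free tables.
    """
    if table is None:
        table = DEFAULT_ATOM_TABLE
    for key, value in table.items():
        if len(value) != 1:
            raise ValueError(f"replacement for {key!r} must be a single character, got {value!r}")
        if value in _RESERVED_SINGLE_CHARS:
            raise ValueError(
                f"replacement character {value!r} for {key!r} collides with an "
                "existing SMILES symbol"
            )
    s = "".join(raw.split())
    keys = sorted(table, key=len, reverse=True)
    out: list[str] = []
    i = 0
    while i < len(s):
        for key in keys:
            if s.startswith(key, i):
                out.append(table[key])
                i += len(key)
                break
        else:
            out.append(s[i])
            i += 1
    return "".join(out)


def zero_ring_numbers(s: str) -> str:
    """Set every ring-closure digit outside square brackets to '0'.

    Digits inside ``[...]`` atom blocks (isotopes, H counts, charges)
    are untouched.  '%nn' two-digit closures become '%00'.  The output
    always has the same length as the input.

    Raises ``ValueError`` naming the position on unbalanced brackets.
    """
    out = list(s)
    depth = 0
    for i, ch in enumerate(s):
        if ch == "[":
            depth += 1
            if depth > 1:
                raise ValueError(f"nested '[' at position {i} in {s!r}")
        elif ch == "]":
            depth -= 1
            if depth < 0:
                raise ValueError(f"unmatched ']' at position {i} in {s!r}")
        elif ch.isdigit() and depth == 0:
            out[i] = "0"
    if depth != 0:
        raise ValueError(f"unclosed '[' in {s!r}")
    return "".join(out)


@dataclass
class CompoundRecord:
    """A compound identifier with its raw and normalized SMILES.

    ``norm_smiles`` is the atom-collapsed string every whole-string
    kernel compares; ``lingo_smiles`` (ring digits zeroed) is computed
    lazily and feeds the LINGO-based kernels.
    """

    id: str
    raw_smiles: str
    norm_smiles: str
    _lingo_smiles: str | None = field(default=None, repr=False, compare=False)

    @property
    def lingo_smiles(self) -> str:
        if self._lingo_smiles is None:
            self._lingo_smiles = zero_ring_numbers(self.norm_smiles)
        return self._lingo_smiles


def make_record(
    compound_id: str, raw_smiles: str, table: Mapping[str, str] | None = None
) -> CompoundRecord:
    """Build a :class:`CompoundRecord`, applying atom collapsing."""
    if not compound_id:
        raise ValueError("compound id must be non-empty")
    return CompoundRecord(
        id=compound_id,
        raw_smiles=raw_smiles,
        norm_smiles=normalize_atoms(raw_smiles, table),
    )


def read_compound_file(
    path: str | Path, table: Mapping[str, str] | None = None
) -> list[CompoundRecord]:
    """Read a two-column ``id<TAB>smiles`` file ('#' lines are comments)."""
    records: list[CompoundRecord] = []
    seen: set[str] = set()
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'id<TAB>smiles', got {line!r}")
        cid, smiles = parts
        if cid in seen:
            raise ValueError(f"{path}:{lineno}: duplicate compound id {cid!r}")
        seen.add(cid)
        records.append(make_record(cid, smiles, table))
    return records


def write_compound_file(path: str | Path, records: Iterable[CompoundRecord]) -> None:
    """Write records as ``id<TAB>raw_smiles`` lines."""
    lines = [f"{r.id}\t{r.raw_smiles}" for r in records]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
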