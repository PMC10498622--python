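"""Resolve a parsed notation against a monomer library.

A :class:`Sequence` is the validated intermediate between line notation and
molecule: an ordered list of monomer entries with global indices, an
explicit bond table (backbone amide bonds R2(i)->R1(i+1) plus the annotated
bonds from ``(n,i)`` pairs), a capping plan for every R-group left unused,
and per-monomer IUPAC atom names.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

from .errors import (
    DoubleBookedRGroupError,
    RGroupError,
    SequenceError,
)
from .monomers import Monomer, MonomerLibrary, get_monomer
from .naming import greekify_monomer
from .notation import PeptideNotation, parse_biln

__all__ = ["Bond", "Sequence", "build_sequence", "greekify_atom_names",
           "validate_sequence"]


@dataclass(frozen=True)
class Bond:
    """A bond between two (monomer index, R-group index) slots."""

    a: tuple[int, int]
    b: tuple[int, int]
    kind: str  # "backbone" | "annotated"


@dataclass
class Sequence:
    monomers: list[Monomer]
    chain_of: list[int]
    bonds: list[Bond]
    #: (monomer index, R-group index) slots capped by their leaving group
    cappings: list[tuple[int, int]] = field(default_factory=list)
    #: per-monomer {atom index in the monomer structure -> IUPAC name}
    atom_names: list[dict[int, str]] = field(default_factory=list)
    library: MonomerLibrary | None = None

    def chain_count(self) -> int:
        return max(self.chain_of) + 1 if self.chain_of else 0

    def amino_acid_indices(self) -> list[int]:
        return [i for i, m in enumerate(self.monomers) if m.role == "amino_acid"]

    def bonded_slots(self) -> set[tuple[int, int]]:
        slots = set()
        for bond in self.bonds:
            slots.add(bond.a)
            slots.add(bond.b)
        return slots

    def to_tsv(self) -> str:
        """Tabular debug dump: index, symbol, chain, bonds."""
        out = io.StringIO()
        out.write("index\tsymbol\tchain\tbonds\n")
        for i, m in enumerate(self.monomers):
            involved = [
                f"{b.kind}:R{b.a[1]}-m{b.b[0]}:R{b.b[1]}" if b.a[0] == i
                else f"{b.kind}:R{b.b[1]}-m{b.a[0]}:R{b.a[1]}"
                for b in self.bonds if i in (b.a[0], b.b[0])
            ]
            out.write(f"{i}\t{m.symbol}\t{self.chain_of[i]}\t"
                      f"{';'.join(involved)}\n")
        return out.getvalue()


def _connector(monomer: Monomer, side: str, index: int) -> int:
    """R-group a monomer uses toward its C-side ('right') or N-side ('left').

    Amino acids use R2 rightward and R1 leftward; a cap uses its single
    R-group on either side.
    """
    if monomer.role == "cap":
        groups = sorted(monomer.r_groups)
        if len(groups) != 1:
            raise SequenceError(
                f"cap {monomer.symbol!r} must expose exactly one R-group"
            )
        return groups[0]
    wanted = 2 if side == "right" else 1
    if wanted not in monomer.r_groups:
        raise RGroupError(monomer.symbol, wanted)
    return wanted


def build_sequence(
    notation: PeptideNotation | str,
    library: MonomerLibrary,
) -> Sequence:
    """Resolve a notation (or BILN string) into a validated Sequence."""
    if isinstance(notation, str):
        notation = parse_biln(notation)

    monomers: list[Monomer] = []
    chain_of: list[int] = []
    global_index: dict[tuple[int, int], int] = {}
    for c_idx, chain in enumerate(notation.chains):
        for p_idx, symbol in enumerate(chain):
            monomer = get_monomer(library, symbol)  # raises on unknown symbol
            if monomer.role == "cap" and 0 < p_idx < len(chain) - 1:
                raise SequenceError(
                    f"cap {symbol!r} appears mid-chain "
                    f"(chain {c_idx + 1}, position {p_idx + 1})"
                )
            global_index[(c_idx, p_idx)] = len(monomers)
            monomers.append(monomer)
            chain_of.append(c_idx)

    bonds: list[Bond] = []
    used_slots: dict[tuple[int, int], str] = {}

    def claim(slot: tuple[int, int], kind: str) -> None:
        if slot in used_slots:
            raise DoubleBookedRGroupError(*slot)
        used_slots[slot] = kind

    # backbone bonds within each chain
    for c_idx, chain in enumerate(notation.chains):
        for p_idx in range(len(chain) - 1):
            i = global_index[(c_idx, p_idx)]
            j = global_index[(c_idx, p_idx + 1)]
            slot_a = (i, _connector(monomers[i], "right", i))
            slot_b = (j, _connector(monomers[j], "left", j))
            claim(slot_a, "backbone")
            claim(slot_b, "backbone")
            bonds.append(Bond(slot_a, slot_b, "backbone"))

    # annotated bonds from (n,i) pairs
    for ann_a, ann_b in notation.bond_pairs():
        slots = []
        for ann in (ann_a, ann_b):
            idx = global_index[(ann.chain, ann.position)]
            if ann.rgroup not in monomers[idx].r_groups:
                raise RGroupError(monomers[idx].symbol, ann.rgroup)
            slots.append((idx, ann.rgroup))
        claim(slots[0], "annotated")
        claim(slots[1], "annotated")
        bonds.append(Bond(slots[0], slots[1], "annotated"))

    cappings = [
        (i, r)
        for i, monomer in enumerate(monomers)
        for r in sorted(monomer.r_groups)
        if (i, r) not in used_slots
    ]

    seq = Sequence(
        monomers=monomers,
        chain_of=chain_of,
        bonds=bonds,
        cappings=cappings,
        library=library,
    )
    return greekify_atom_names(seq)


def greekify_atom_names(seq: Sequence) -> Sequence:
    """Populate per-monomer IUPAC atom names (idempotent)."""
    seq.atom_names = [greekify_monomer(m) for m in seq.monomers]
    return seq


def validate_sequence(seq: Sequence) -> list[str]:
    """Check the Sequence invariants; return human-readable violations."""
    violations: list[str] = []
    n = len(seq.monomers)
    if len(seq.chain_of) != n:
        violations.append("chain_of: length does not match monomer count")
        return violations

    slot_use: dict[tuple[int, int], int] = {}
    backbone_pairs = set()
    for bond in seq.bonds:
        for idx, rgroup in (bond.a, bond.b):
            if not (0 <= idx < n):
                violations.append(
                    f"bonds: monomer index {idx} out of range"
                )
                continue
            if rgroup not in seq.monomers[idx].r_groups:
                violations.append(
                    f"bonds: monomer {idx} ({seq.monomers[idx].symbol}) "
                    f"has no R{rgroup}"
                )
            slot_use[(idx, rgroup)] = slot_use.get((idx, rgroup), 0) + 1
        if bond.a == bond.b:
            violations.append("bonds: bond connects a slot to itself")
        if bond.kind == "backbone":
            backbone_pairs.add(frozenset((bond.a[0], bond.b[0])))

    for slot, count in slot_use.items():
        if count > 1:
            violations.append(
                f"bonds: R{slot[1]} of monomer {slot[0]} used by "
                f"{count} bonds"
            )

    # consecutive amino acids within a chain must share one backbone bond
    for i in range(n - 1):
        if seq.chain_of[i] != seq.chain_of[i + 1]:
            continue
        if frozenset((i, i + 1)) not in backbone_pairs:
            violations.append(
                f"bonds: consecutive monomers {i} and {i + 1} in chain "
                f"{seq.chain_of[i]} lack a backbone bond"
            )

    # every R-group is either bonded or scheduled for capping
    capped = set(seq.cappings)
    for i, monomer in enumerate(seq.monomers):
        for r in monomer.r_groups:
            slot = (i, r)
            in_bond = slot in slot_use
            if in_bond and slot in capped:
                violations.append(
                    f"cappings: R{r} of monomer {i} is both bonded and capped"
                )
            if not in_bond and slot not in capped:
                violations.append(
                    f"cappings: R{r} of monomer {i} is neither bonded nor "
                    "scheduled for capping"
                )
    return violations
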