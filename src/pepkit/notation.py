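"""Peptide line notations.

BILN is the native format: monomer symbols joined by ``-`` within a chain,
chains joined by ``.``, and paired bond annotations ``m(n,i)`` declaring
that this monomer takes part in inter-monomer bond ``n`` through its
R-group ``i``.  Each bond id must occur exactly twice across the whole
string.  HELM v2 peptide strings (``PEPTIDEk{...}`` polymers, a ``$``
-delimited connections section and a ``V2.0`` suffix) convert losslessly to
and from BILN; FASTA converts one way, since it carries no branching or
cyclization information.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import NotationError, UnpairedBondError

__all__ = [
    "BondAnnotation",
    "PeptideNotation",
    "parse_biln",
    "write_biln",
    "helm_to_biln",
    "biln_to_helm",
    "fasta_to_biln",
]

STANDARD_LETTERS = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class BondAnnotation:
    """One end of an inter-monomer bond: ``(n, i)`` on a specific monomer."""

    bond_id: int
    rgroup: int
    chain: int  # 0-based chain index
    position: int  # 0-based monomer position within the chain


@dataclass
class PeptideNotation:
    chains: list[list[str]] = field(default_factory=list)
    annotations: list[BondAnnotation] = field(default_factory=list)

    def residue_count(self) -> int:
        return sum(len(c) for c in self.chains)

    def bond_pairs(self) -> list[tuple[BondAnnotation, BondAnnotation]]:
        """Annotations grouped into pairs by bond id, in id order."""
        by_id: dict[int, list[BondAnnotation]] = {}
        for ann in self.annotations:
            by_id.setdefault(ann.bond_id, []).append(ann)
        pairs = []
        for bond_id in sorted(by_id):
            group = by_id[bond_id]
            if len(group) != 2:
                raise UnpairedBondError(bond_id, len(group))
            pairs.append((group[0], group[1]))
        return pairs


_TOKEN_RE = re.compile(
    r"^\s*(?P<symbol>[^()\s]+?)\s*(?P<anns>(?:\(\s*\d+\s*,\s*\d+\s*\)\s*)*)$"
)
_ANN_RE = re.compile(r"\(\s*(\d+)\s*,\s*(\d+)\s*\)")


def _split_top(text: str, sep: str) -> list[str]:
    """Split on ``sep`` outside parentheses."""
    parts, depth, buf = [], 0, []
    for ch in text:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth = max(0, depth - 1)
        if ch == sep and depth == 0:
            parts.append("".join(buf))
            buf = []
        else:
            buf.append(ch)
    parts.append("".join(buf))
    return parts


def parse_biln(text: str) -> PeptideNotation:
    """Parse a BILN string, validating the bond-id pairing."""
    if text is None or not text.strip():
        raise NotationError("empty BILN string")
    notation = PeptideNotation()
    for c_idx, chain_text in enumerate(_split_top(text.strip(), ".")):
        if not chain_text.strip():
            raise NotationError(f"empty chain at position {c_idx + 1} (dangling '.')")
        chain: list[str] = []
        for p_idx, token in enumerate(_split_top(chain_text, "-")):
            token = token.strip()
            if not token:
                raise NotationError(
                    f"empty monomer token in chain {c_idx + 1} (dangling '-')"
                )
            m = _TOKEN_RE.match(token)
            if m is None:
                raise NotationError(f"malformed monomer token {token!r}")
            symbol = m.group("symbol")
            chain.append(symbol)
            for n, i in _ANN_RE.findall(m.group("anns") or ""):
                bond_id, rgroup = int(n), int(i)
                if bond_id < 1 or rgroup < 1:
                    raise NotationError(
                        f"bond annotation ({n},{i}) on {symbol!r}: indices "
                        "must be positive"
                    )
                notation.annotations.append(
                    BondAnnotation(bond_id, rgroup, c_idx, p_idx)
                )
        notation.chains.append(chain)
    _check_bond_ids(notation)
    return notation


def _check_bond_ids(notation: PeptideNotation) -> None:
    counts: dict[int, int] = {}
    for ann in notation.annotations:
        counts[ann.bond_id] = counts.get(ann.bond_id, 0) + 1
    for bond_id, count in sorted(counts.items()):
        if count != 2:
            raise UnpairedBondError(bond_id, count)


def write_biln(notation: PeptideNotation) -> str:
    """Serialize to canonical BILN (no whitespace)."""
    if not notation.chains or any(not c for c in notation.chains):
        raise NotationError("notation has an empty chain")
    _check_bond_ids(notation)
    ann_at: dict[tuple[int, int], list[BondAnnotation]] = {}
    for ann in notation.annotations:
        c, p = ann.chain, ann.position
        if not (0 <= c < len(notation.chains) and 0 <= p < len(notation.chains[c])):
            raise NotationError(
                f"annotation ({ann.bond_id},{ann.rgroup}) references "
                f"nonexistent monomer (chain {c + 1}, position {p + 1})"
            )
        ann_at.setdefault((c, p), []).append(ann)
    chains_out = []
    for c_idx, chain in enumerate(notation.chains):
        tokens = []
        for p_idx, symbol in enumerate(chain):
            if not symbol:
                raise NotationError("empty monomer token")
            suffix = "".join(
                f"({a.bond_id},{a.rgroup})" for a in ann_at.get((c_idx, p_idx), [])
            )
            tokens.append(symbol + suffix)
        chains_out.append("-".join(tokens))
    return ".".join(chains_out)


# --- HELM ------------------------------------------------------------------

_POLYMER_RE = re.compile(r"^\s*([A-Za-z]+)(\d+)\s*\{(.*)\}\s*$", re.S)
_CONNECTION_RE = re.compile(
    r"^\s*([A-Za-z]+\d+)\s*,\s*([A-Za-z]+\d+)\s*,\s*"
    r"(\d+)\s*:\s*R(\d+)\s*-\s*(\d+)\s*:\s*R(\d+)\s*$"
)


def _split_helm_monomers(content: str) -> list[str]:
    tokens, buf, depth = [], [], 0
    for ch in content:
        if ch == "[":
            depth += 1
            continue
        if ch == "]":
            depth -= 1
            if depth < 0:
                raise NotationError("unbalanced brackets in HELM polymer")
            continue
        if ch == "." and depth == 0:
            tokens.append("".join(buf).strip())
            buf = []
        else:
            buf.append(ch)
    tokens.append("".join(buf).strip())
    if any(not t for t in tokens):
        raise NotationError("empty monomer token in HELM polymer")
    return tokens


def helm_to_biln(helm: str) -> str:
    """Convert a HELM v2 peptide string to canonical BILN.

    Only PEPTIDE polymers are supported; connections become paired ``(n,i)``
    annotations with fresh consecutive bond ids.
    """
    if not helm or not helm.strip():
        raise NotationError("empty HELM string")
    sections = helm.strip().split("$")
    if len(sections) < 2:
        raise NotationError("HELM string lacks '$'-delimited sections")
    polymer_section = sections[0].strip()
    connection_section = sections[1].strip() if len(sections) > 1 else ""

    notation = PeptideNotation()
    polymer_ids: dict[str, int] = {}
    for chunk in polymer_section.split("|"):
        m = _POLYMER_RE.match(chunk)
        if m is None:
            raise NotationError(f"malformed polymer section: {chunk.strip()!r}")
        ptype, pnum, content = m.group(1), m.group(2), m.group(3)
        if ptype.upper() != "PEPTIDE":
            raise NotationError(
                f"unsupported polymer type {ptype!r}; only PEPTIDE is handled"
            )
        polymer_ids[f"{ptype.upper()}{pnum}"] = len(notation.chains)
        notation.chains.append(_split_helm_monomers(content))

    bond_id = 0
    if connection_section:
        for chunk in connection_section.split("|"):
            m = _CONNECTION_RE.match(chunk)
            if m is None:
                raise NotationError(
                    f"malformed connection triplet: {chunk.strip()!r}"
                )
            p1, p2 = m.group(1).upper(), m.group(2).upper()
            for p in (p1, p2):
                if p not in polymer_ids:
                    raise NotationError(
                        f"connection references unknown polymer {p!r}"
                    )
            bond_id += 1
            for polymer, pos, rg in (
                (p1, int(m.group(3)), int(m.group(4))),
                (p2, int(m.group(5)), int(m.group(6))),
            ):
                chain = polymer_ids[polymer]
                if not (1 <= pos <= len(notation.chains[chain])):
                    raise NotationError(
                        f"connection references monomer {pos} outside "
                        f"{polymer} (length {len(notation.chains[chain])})"
                    )
                notation.annotations.append(
                    BondAnnotation(bond_id, rg, chain, pos - 1)
                )
    return write_biln(notation)


def biln_to_helm(biln: str) -> str:
    """Convert BILN to a HELM v2 peptide string (single connections field,
    ``V2.0`` suffix, multi-character symbols bracketed)."""
    notation = parse_biln(biln)
    polymers = []
    for chain in notation.chains:
        tokens = [t if len(t) == 1 else f"[{t}]" for t in chain]
        polymers.append(f"PEPTIDE{len(polymers) + 1}{{{'.'.join(tokens)}}}")
    connections = []
    for a, b in notation.bond_pairs():
        connections.append(
            f"PEPTIDE{a.chain + 1},PEPTIDE{b.chain + 1},"
            f"{a.position + 1}:R{a.rgroup}-{b.position + 1}:R{b.rgroup}"
        )
    return f"{'|'.join(polymers)}${'|'.join(connections)}$$$V2.0"


def fasta_to_biln(fasta: str) -> str:
    """Convert a FASTA record (header optional) to a linear BILN chain."""
    if not fasta or not fasta.strip():
        raise NotationError("empty FASTA input")
    seq_parts = [
        line.strip()
        for line in fasta.strip().splitlines()
        if line.strip() and not line.lstrip().startswith(">")
    ]
    sequence = "".join(seq_parts)
    if not sequence:
        raise NotationError("FASTA input contains no sequence")
    for pos, letter in enumerate(sequence, start=1):
        if letter.upper() not in STANDARD_LETTERS:
            raise NotationError(
                f"non-standard residue letter {letter!r} at position {pos}"
            )
    return "-".join(sequence.upper())
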