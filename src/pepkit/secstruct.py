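"""Secondary-structure prediction by ungapped fragment matching.

A query peptide is compared, without gaps, against every entry of a
reference database of (sequence, per-residue DSSP-category string) pairs.
For two equal-length fragments A and B the similarity is the normalized
substitution-matrix score

    s_AB = score_AB / sqrt(score_AA * score_BB)

which is 1 for identical fragments and symmetric.  When the query is
shorter than a database sequence it slides over the entry's windows; when
longer, entry-length windows slide over the query.  Windows scoring at or
above the threshold (default 0.65, the midpoint of the useful 0.6-0.7
band) contribute their annotation fragment to a per-position vote profile,
and each query position takes the most frequent category, ``-`` where no
hit covers it.

Non-natural residues take part through their natural analogs — an
explicit annotation if the monomer dictionary has one, otherwise the
fingerprint-nearest standard residue (alanine as a last resort).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from Bio.Align import substitution_matrices

from .errors import PepkitError
from .monomers import assign_natural_analog
from .sequence import Sequence

__all__ = [
    "ReferenceEntry",
    "ReferenceDB",
    "MatchHit",
    "SSAnnotation",
    "similarity_score",
    "match_query",
    "predict_secstruct",
    "natural_query",
    "load_reference_db",
    "default_matrix",
]

SS_CATEGORIES = "HEBSTG-"
#: vote tie priority: helix and strand first (they drive 3D restraints)
TIE_PRIORITY = "HEGTSB-"


@dataclass(frozen=True)
class ReferenceEntry:
    sequence: str
    ss: str

    def __post_init__(self):
        if not self.sequence or len(self.sequence) != len(self.ss):
            raise PepkitError(
                f"reference entry {self.sequence!r}: sequence and ss must be "
                "non-empty and of equal length"
            )


@dataclass
class ReferenceDB:
    entries: list[ReferenceEntry] = field(default_factory=list)

    @property
    def max_len(self) -> int:
        return max((len(e.sequence) for e in self.entries), default=0)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class MatchHit:
    query_span: tuple[int, int]  # half-open
    db_entry: int
    db_span: tuple[int, int]  # half-open
    s_ab: float
    ss_fragment: str


@dataclass(frozen=True)
class SSAnnotation:
    categories: str

    def __len__(self) -> int:
        return len(self.categories)

    def __str__(self) -> str:
        return self.categories


def default_matrix():
    """BLOSUM62; the matrix is a parameter everywhere it is used."""
    return substitution_matrices.load("BLOSUM62")


def _pair_score(a: str, b: str, matrix) -> float:
    return float(sum(matrix[x][y] for x, y in zip(a, b)))


def similarity_score(a: str, b: str, matrix=None) -> float:
    """Normalized ungapped similarity of two equal-length sequences."""
    if not a or len(a) != len(b):
        raise PepkitError("similarity_score requires equal-length, non-empty "
                          f"sequences (got {len(a or '')} and {len(b or '')})")
    matrix = default_matrix() if matrix is None else matrix
    score_aa = _pair_score(a, a, matrix)
    score_bb = _pair_score(b, b, matrix)
    if score_aa <= 0 or score_bb <= 0:
        raise PepkitError(
            "non-positive self-score; normalization undefined for "
            f"{a!r} / {b!r}"
        )
    return _pair_score(a, b, matrix) / math.sqrt(score_aa * score_bb)


def match_query(
    query: str,
    db: ReferenceDB,
    matrix=None,
    threshold: float = 0.65,
) -> list[MatchHit]:
    """All ungapped windows with similarity at or above the threshold."""
    if not query:
        raise PepkitError("empty query")
    matrix = default_matrix() if matrix is None else matrix
    hits: list[MatchHit] = []
    nq = len(query)
    for e_idx, entry in enumerate(db.entries):
        ne = len(entry.sequence)
        if nq <= ne:
            for start in range(ne - nq + 1):
                frag = entry.sequence[start:start + nq]
                s = similarity_score(query, frag, matrix)
                if s >= threshold:
                    hits.append(MatchHit(
                        query_span=(0, nq),
                        db_entry=e_idx,
                        db_span=(start, start + nq),
                        s_ab=s,
                        ss_fragment=entry.ss[start:start + nq],
                    ))
        else:
            for start in range(nq - ne + 1):
                frag = query[start:start + ne]
                s = similarity_score(frag, entry.sequence, matrix)
                if s >= threshold:
                    hits.append(MatchHit(
                        query_span=(start, start + ne),
                        db_entry=e_idx,
                        db_span=(0, ne),
                        s_ab=s,
                        ss_fragment=entry.ss,
                    ))
    return hits


def natural_query(seq: Sequence) -> str:
    """One-letter natural-analog string for the amino-acid monomers."""
    letters = []
    for i in seq.amino_acid_indices():
        monomer = seq.monomers[i]
        if monomer.symbol in "ACDEFGHIKLMNPQRSTVWY" and len(monomer.symbol) == 1:
            letters.append(monomer.symbol)
        elif seq.library is not None:
            letters.append(assign_natural_analog(monomer, seq.library))
        else:
            letters.append(monomer.natural_analog or "A")
    return "".join(letters)


def predict_secstruct(
    query,
    db: ReferenceDB,
    matrix=None,
    threshold: float = 0.65,
    weight_by_score: bool = False,
) -> SSAnnotation:
    """Per-residue secondary-structure categories for a query.

    ``query`` is a :class:`~pepkit.sequence.Sequence` (non-natural residues
    are mapped to natural analogs first) or a plain one-letter string.
    Votes from hits are unweighted by default; ``weight_by_score`` weights
    each hit's votes by its similarity.
    """
    if isinstance(query, Sequence):
        query = natural_query(query)
    if not query:
        raise PepkitError("empty query")
    if not (5 <= len(query) <= 20):
        warnings.warn(
            f"query length {len(query)} outside the recommended 5-20 range"
        )
    votes: list[dict[str, float]] = [dict() for _ in query]
    for hit in match_query(query, db, matrix, threshold):
        weight = hit.s_ab if weight_by_score else 1.0
        q0, _ = hit.query_span
        for offset, category in enumerate(hit.ss_fragment):
            tally = votes[q0 + offset]
            tally[category] = tally.get(category, 0.0) + weight
    out = []
    for tally in votes:
        if not tally:
            out.append("-")
            continue
        best = max(tally.values())
        winners = [c for c, v in tally.items() if v >= best - 1e-12]
        out.append(min(winners, key=lambda c: TIE_PRIORITY.index(c)
                       if c in TIE_PRIORITY else len(TIE_PRIORITY)))
    return SSAnnotation("".join(out))


def load_reference_db(source) -> ReferenceDB:
    """Read a reference database from TSV (sequence<TAB>ss) or FASTA with
    ``ss=`` annotations in the header; duplicates keep the first entry."""
    text = source.read() if hasattr(source, "read") else source
    if "\n" not in text and text.endswith((".tsv", ".fasta", ".fa", ".txt")):
        with open(text) as fh:
            text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    records: list[tuple[str, str]] = []
    if lines and lines[0].startswith(">"):
        header = None
        for ln in lines:
            if ln.startswith(">"):
                header = ln
            else:
                if header is None or "ss=" not in header:
                    raise PepkitError(
                        "FASTA reference record lacks an ss= annotation"
                    )
                ss = header.split("ss=", 1)[1].split()[0]
                records.append((ln.strip(), ss))
                header = None
    else:
        for i, ln in enumerate(lines):
            parts = ln.split("\t")
            if len(parts) != 2:
                raise PepkitError(f"record {i}: expected two TSV columns")
            records.append((parts[0].strip(), parts[1].strip()))
    db = ReferenceDB()
    seen = set()
    for i, (seq, ss) in enumerate(records):
        if len(seq) != len(ss):
            raise PepkitError(
                f"record {i}: sequence length {len(seq)} != ss length {len(ss)}"
            )
        if seq in seen:
            warnings.warn(f"duplicate reference sequence {seq!r}; keeping the "
                          "first occurrence")
            continue
        seen.add(seq)
        db.entries.append(ReferenceEntry(seq, ss))
    return db
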