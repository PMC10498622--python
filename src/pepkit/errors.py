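"""Exception hierarchy.

Every user-facing failure mode raises a named subclass of :class:`PepkitError`
so callers (and the CLI) can distinguish malformed notation from library
lookup failures from chemistry-level problems.
"""


class PepkitError(Exception):
    """Base class for all package errors."""


class NotationError(PepkitError):
    """Malformed BILN/HELM/FASTA input."""


class UnpairedBondError(NotationError):
    """A bond id does not occur exactly twice in a notation."""

    def __init__(self, bond_id: int, count: int):
        self.bond_id = bond_id
        self.count = count
        super().__init__(
            f"bond id {bond_id} occurs {count} time(s); "
            "the correct number of bond identifiers is exactly two"
        )


class MonomerError(PepkitError):
    """Problems with monomer records or libraries."""


class MonomerNotFoundError(MonomerError):
    """Lookup of an unknown monomer symbol."""

    def __init__(self, symbol: str):
        self.symbol = symbol
        super().__init__(f"monomer symbol {symbol!r} is not in the library")


class MonomerIngestError(MonomerError):
    """An SDF record could not be turned into a valid monomer entry."""


class DuplicateSymbolError(MonomerIngestError):
    def __init__(self, symbol: str, first: int, second: int):
        self.symbol = symbol
        super().__init__(
            f"duplicate monomer symbol {symbol!r} in records {first} and {second}"
        )


class SequenceError(PepkitError):
    """Errors while resolving a notation against a library."""


class RGroupError(SequenceError):
    """An annotation references an R-group the monomer does not expose."""

    def __init__(self, symbol: str, rgroup: int):
        self.symbol = symbol
        self.rgroup = rgroup
        super().__init__(f"monomer {symbol!r} has no R{rgroup} attachment point")


class DoubleBookedRGroupError(SequenceError):
    """The same (monomer, R-group) slot is used by more than one bond."""

    def __init__(self, monomer_index: int, rgroup: int):
        self.monomer_index = monomer_index
        self.rgroup = rgroup
        super().__init__(
            f"R{rgroup} of monomer {monomer_index} is used by more than one bond"
        )


class AssemblyError(PepkitError):
    """Chemistry-level failure while building the molecular graph."""


class EmbeddingError(PepkitError):
    """3D embedding failed after the retry budget."""


class SSLengthError(PepkitError):
    """A secondary-structure string does not match the residue count."""

    def __init__(self, expected: int, got: int):
        self.expected = expected
        self.got = got
        super().__init__(
            f"secondary-structure string length {got} does not match "
            f"residue count {expected}"
        )
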