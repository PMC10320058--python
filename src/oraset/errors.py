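"""Exception hierarchy shared across the package."""

from __future__ import annotations


class OrasetError(Exception):
    """Base class for all package-specific errors."""


class ParseError(OrasetError):
    """A file could not be parsed; carries the path and 1-based line number."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f" [{path}"
            loc += f":{line}]" if line is not None else "]"
        elif line is not None:
            loc = f" [line {line}]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class OntologyCycleError(OrasetError):
    """Parent links form a directed cycle; the ontology is not a DAG."""

    def __init__(self, cycle: list[str]):
        super().__init__("ontology parent links form a cycle: " + " -> ".join(cycle))
        self.cycle = cycle


class TermNotFoundError(OrasetError, KeyError):
    """A term accession is neither a primary id nor an alt_id."""

    def __init__(self, term_id: str):
        OrasetError.__init__(self, f"unknown term id: {term_id!r}")
        self.term_id = term_id


class SetNotFoundError(OrasetError, KeyError):
    """A gene-set id is not present in the collection/results."""

    def __init__(self, set_id: str):
        OrasetError.__init__(self, f"unknown gene set id: {set_id!r}")
        self.set_id = set_id


class ConfigurationError(OrasetError):
    """An invalid mode, threshold or parameter combination."""


class DomainError(OrasetError, ValueError):
    """A numeric argument violates its precondition; names the offender."""


class EmptyInputError(OrasetError):
    """The input gene list is empty after background intersection."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
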