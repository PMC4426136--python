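"""Exception hierarchy with stable machine-readable error codes.

Every user-facing failure carries a ``code`` string so the CLI can emit both
human-readable text and structured (``--json``) diagnostics without string
matching on messages.
"""

from __future__ import annotations


class TpmError(ValueError):
    """Base class for all toolkit errors.

    Parameters
    ----------
    code : str
        Stable machine-readable identifier (kebab-case).
    message : str
        Human-readable explanation.
    """

    def __init__(self, code: str, message: str):
        super().__init__(message)
        self.code = code
        self.message = message

    def __str__(self) -> str:  # pragma: no cover - trivial
        return f"[{self.code}] {self.message}"


class NomenclatureError(TpmError):
    """Malformed isoform name or exon-usage code."""


class RegistryError(TpmError):
    """Packaged or user-supplied registry data violates its schema."""


class AssemblyError(TpmError):
    """Protein assembly cannot proceed (missing/invalid segments)."""


class NomenclatureWarning(UserWarning):
    """Non-fatal normalisation applied while parsing (e.g. known typo dialects)."""


# Error codes used across the package (documented here for discoverability).
EMPTY_INPUT = "empty-input"
MALFORMED_NAME = "malformed-name"
BAD_PREFIX = "bad-prefix"
GENE_OUT_OF_RANGE = "gene-out-of-range"
BAD_ORDINAL = "bad-ordinal"
UNKNOWN_TISSUE = "unknown-tissue"
BAD_TOKEN_COUNT = "bad-token-count"
BAD_EXON_TOKEN = "bad-exon-token"
LINKAGE_VIOLATION = "linkage-violation"
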