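"""Exception hierarchy shared across the package."""


class PssmBindError(Exception):
    """Base class for all package-specific errors."""


class AlphabetError(PssmBindError, ValueError):
    """A sequence contains a character outside the 20 canonical amino acids."""


class LengthError(PssmBindError, ValueError):
    """A peptide length is outside the supported range or mismatched."""


class AlleleFormatError(PssmBindError, ValueError):
    """An allele name could not be parsed into the canonical two-field form."""


class PssmParseError(PssmBindError, ValueError):
    """A PSSM file is malformed; message names the file and offending line."""


class SchemaError(PssmBindError, ValueError):
    """A tabular input is missing required columns or has malformed rows."""


class UncoverableAlleleError(PssmBindError, LookupError):
    """No usable similarity neighbor exists for an uncharacterized allele."""


class UndefinedMetricError(PssmBindError, ValueError):
    """A metric is undefined for the given input (e.g. single-class AUC)."""


class RejectionBudgetError(PssmBindError, RuntimeError):
    """Rejection sampling exhausted its attempt budget."""
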