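"""Exception hierarchy shared by the pipeline stages."""


class EndoGeneError(Exception):
    """Base class for all errors raised by this package."""


class TableParseError(EndoGeneError):
    """Input file could not be parsed (names the offending row/column)."""


class TableValidationError(EndoGeneError):
    """Parsed table violates the Cq-table column contract."""


class PanelError(EndoGeneError):
    """Invalid gene-role assignment (unknown genes, empty reference set)."""


class ParameterError(EndoGeneError):
    """Out-of-range analysis parameter (e.g. non-positive SD threshold)."""


class ContractError(EndoGeneError):
    """Analysis precondition not met (group counts, gene counts, sizes)."""
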