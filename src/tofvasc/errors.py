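"""Exception hierarchy shared by all pipeline stages."""


class TofVascError(Exception):
    """Base class for all tofvasc errors."""


class ValidationError(TofVascError):
    """Input violates a structural contract (shape, grid, mask, affine)."""


class ParameterError(TofVascError):
    """A parameter value is outside its allowed domain."""


class DegenerateInputError(TofVascError):
    """Input is formally valid but degenerate for the operation (e.g. constant)."""


class ProcessingError(TofVascError):
    """A stage produced an unusable intermediate (e.g. empty body mask)."""


class SchemaError(TofVascError):
    """A tabular input is missing required columns."""
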