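"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A configuration object violates one of its invariants."""


class ConvergenceError(RuntimeError):
    """An iterative fit failed to converge within its iteration budget."""


class CollinearityError(ValueError):
    """A design matrix contains aliased (collinear) columns."""
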