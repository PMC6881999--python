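"""Exception types shared across the package."""


class MalformedInputError(ValueError):
    """Structurally invalid input (wrong item count, duplicate visits, ...).

    Distinct from missing data, which is handled by the scoring and
    exclusion rules rather than raised.
    """


class DegenerateReferenceError(ValueError):
    """A composite reference component has too few values or zero variance."""


class CollinearityError(ValueError):
    """Design matrix is rank deficient; carries the offending column name."""

    def __init__(self, column: str):
        self.column = column
        super().__init__(f"design matrix is rank deficient: column {column!r} "
                         "is collinear with preceding columns")


class EmptyStratumError(RuntimeError):
    """A stratum specification selected zero usable rows."""

    def __init__(self, spec):
        self.spec = spec
        super().__init__(f"no rows left after filtering for stratum {spec}")
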