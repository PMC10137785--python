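"""Exception hierarchy for fullsib."""


class FullSibError(Exception):
    """Base class for all fullsib errors."""


class InvalidDesignError(FullSibError, ValueError):
    """The nested family structure is malformed (empty strata, bad counts)."""


class DegreesOfFreedomError(InvalidDesignError):
    """A stratum of the hierarchical ANOVA has no degrees of freedom."""


class UnsupportedConfigurationError(FullSibError, ValueError):
    """A configuration the analytic formulas do not cover, e.g. unbalanced
    within-dam family sizes combined with a nonzero AR coefficient."""


class UndefinedHeritabilityError(FullSibError, ZeroDivisionError):
    """Phenotypic variance is zero, so heritability ratios are undefined."""


class RecordsError(FullSibError, ValueError):
    """A phenotype record file violates the records contract."""


class RankDeficiencyError(FullSibError, ValueError):
    """The MINQUE0 normal equations are singular for this design."""


class CellError(FullSibError, RuntimeError):
    """Every replicate of a Monte Carlo cell failed."""
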