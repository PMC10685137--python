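"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """An invalid simulation or pipeline configuration."""


class EstimationError(RuntimeError):
    """A model fit failed (singular design, non-convergence, empty data)."""


class MotherMismatchError(ValueError):
    """Offspring genotype is Mendelian-impossible given the mother at zero
    genotyping error (zero likelihood under the null-father model)."""
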