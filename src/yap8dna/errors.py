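"""Exception hierarchy for the yap8dna toolkit."""


class Yap8DnaError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(Yap8DnaError):
    """A user-supplied configuration (chain-role map, thresholds, region
    annotations ...) is missing or inconsistent."""


class FormatError(Yap8DnaError):
    """An input file violates its format contract (duplicate serials,
    per-model atom-count mismatch ...)."""


class SelectionError(Yap8DnaError):
    """A selection expression could not be parsed."""


class ValidationError(Yap8DnaError):
    """A domain object violates its invariants (bad motif alphabet,
    wrong sequence length ...)."""


class FitError(Yap8DnaError):
    """Nonlinear least-squares fitting failed to converge."""


class DegenerateDataError(FitError):
    """The data carry no signal to fit (e.g. an all-zero titration)."""


class GeneratorError(Yap8DnaError):
    """A synthetic-data specification is internally inconsistent (e.g.
    planted geometries that do not respect the detection margins)."""


class NoClusterError(Yap8DnaError):
    """A representative structure was requested from an all-noise
    clustering result."""
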