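"""Exception hierarchy for gene-set distance analysis.

All errors raised by the package derive from :class:`GSDAError` so callers
can catch everything with one clause; the CLI maps them to one-line
diagnostics and a nonzero exit code.
"""


class GSDAError(Exception):
    """Base class for all errors raised by this package."""


class InputError(GSDAError):
    """Malformed, missing, or non-numeric input data."""


class SampleSizeError(InputError):
    """Too few subjects: the bias-corrected inner product requires n >= 4."""


class DegenerateError(GSDAError):
    """A distance structure carries no information (zero self inner product)."""


class DegenerateGeneSetError(DegenerateError):
    """All pairwise expression distances for the gene set are (numerically) zero."""


class DegenerateEndpointError(DegenerateError):
    """The endpoint admits no pairwise contrast (e.g. a single category, no events)."""


class GeneMatchingError(GSDAError):
    """No gene of the requested gene set is present in the expression matrix."""


class ZeroVarianceError(InputError):
    """One or more genes have zero sample variance, so the transform is undefined."""

    def __init__(self, genes):
        self.genes = list(genes)
        super().__init__(
            "zero-variance gene(s): " + ", ".join(str(g) for g in self.genes)
        )
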