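"""Exception hierarchy shared across the package."""


class EcodemandError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(EcodemandError, ValueError):
    """Malformed or out-of-domain input (bad labels, nonpositive mass, ...)."""


class CatalogueLookupError(EcodemandError, KeyError):
    """No allometric model published for the requested key."""

    def __init__(self, resource, taxon_class, trophic):
        self.key = (resource, taxon_class, trophic)
        super().__init__(
            f"no allometric model for resource={resource!r}, "
            f"class={taxon_class!r}, trophic={trophic!r}"
        )


class FitError(EcodemandError):
    """A regression group could not be fitted (too few points, degenerate masses)."""


class SurveyFormatError(EcodemandError):
    """A survey or density file failed validation; carries per-row messages."""

    def __init__(self, message, row_errors=()):
        self.row_errors = list(row_errors)
        detail = "; ".join(self.row_errors)
        super().__init__(message if not detail else f"{message}: {detail}")
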