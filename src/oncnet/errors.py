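"""Exception types shared across the pipeline."""


class OncnetError(Exception):
    """Base class for package errors."""


class InvalidConfigError(OncnetError):
    """A configuration value is out of range or inconsistent."""


class InvalidInputError(OncnetError):
    """An operation received inputs violating its contract."""


class ReferentialIntegrityError(OncnetError):
    """A table references ids absent from its companion table."""


class UnmappedZipError(OncnetError):
    """A billing ZIP is missing from the geographic crosswalk."""

    def __init__(self, zips):
        self.zips = sorted(set(zips))
        super().__init__(f"ZIPs missing from crosswalk: {', '.join(self.zips)}")


class MissingNodeError(OncnetError):
    """A network measure was requested for a node not in the graph."""


class FitFailureError(OncnetError):
    """A statistical model could not be fitted."""


class DegenerateStructureError(OncnetError):
    """Random-effect structure has too few levels to be estimated."""
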