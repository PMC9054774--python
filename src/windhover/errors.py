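"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: validation problems exit with 2,
stage failures inside the pipeline exit with 3.
"""


class WindhoverError(Exception):
    """Base class for all package errors."""


class ValidationError(WindhoverError, ValueError):
    """Invalid parameters, specs or malformed inputs."""


class FormatError(ValidationError):
    """A file does not conform to the expected on-disk format."""


class OutOfDomainError(WindhoverError, ValueError):
    """A query point lies outside the supported domain (no extrapolation)."""


class MissingNodeError(ValidationError):
    """A rectangular lattice is incomplete; carries the absent coordinates."""

    def __init__(self, missing):
        self.missing = list(missing)
        coords = ", ".join(f"({x:g}, {z:g})" for x, z in self.missing)
        super().__init__(f"lattice is missing {len(self.missing)} node(s): {coords}")


class StageError(WindhoverError, RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage, cause):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
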