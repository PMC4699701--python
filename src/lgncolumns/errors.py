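"""Exception hierarchy for the projection-column pipeline."""


class LgnError(Exception):
    """Base class for all package errors."""


class TableParseError(LgnError):
    """A delimited text table failed to parse.

    Carries the file path and 1-based line number of the offending row so
    that hand-curated cell tables can be fixed quickly.
    """

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        prefix = ""
        if path is not None:
            prefix += str(path)
        if line is not None:
            prefix += f":{line}"
        if prefix:
            prefix += ": "
        super().__init__(prefix + message)


class MeshValidationError(LgnError):
    """Nucleus surface mesh violates a structural requirement."""


class ConfigError(LgnError):
    """Pipeline configuration is missing or inconsistent."""


class StageError(LgnError):
    """A pipeline stage failed; names the stage and the offending animal."""

    def __init__(self, stage: str, animal_id: str | None, cause: Exception):
        self.stage = stage
        self.animal_id = animal_id
        self.cause = cause
        who = f" (animal_id={animal_id})" if animal_id else ""
        super().__init__(f"stage '{stage}' failed{who}: {cause}")


class DegenerateGeometryError(LgnError):
    """Point configuration is rank-deficient for the requested fit."""


class NoIntersectionError(LgnError):
    """An extended column trajectory never crosses the nucleus surface."""


class AmbiguousBoundaryError(LgnError):
    """Pial/ventral assignment of the boundary crossings is ambiguous."""


class ZeroDistanceError(LgnError):
    """Coincident points within one space; neighbour ranks undefined."""


class MissingMetricError(LgnError):
    """A group lacks one of the four depth-profile metrics."""


class MissingInjectionError(LgnError):
    """A mapped column has no matching V1 injection record."""
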