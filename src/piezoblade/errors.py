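"""Exception hierarchy for the piezoblade pipeline."""


class PiezobladeError(Exception):
    """Base class for all piezoblade errors."""


class CalibrationError(PiezobladeError):
    """Generator calibration did not reach the requested targets."""


class SceneError(PiezobladeError):
    """Ground-truth scene could not be constructed (e.g. placement failure)."""


class SchemaError(PiezobladeError):
    """A localization table violates the documented schema."""


class ConfigError(PiezobladeError):
    """A configuration value is missing, unknown, or out of range."""


class GeometryError(PiezobladeError):
    """Degenerate geometry (e.g. collinear fluorophore centres)."""


class FitError(PiezobladeError):
    """A model fit failed to converge or the input was degenerate."""


class PipelineError(PiezobladeError):
    """A pipeline stage received input it cannot process."""
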