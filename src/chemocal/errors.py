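"""Exception hierarchy for chemocal."""


class ChemocalError(Exception):
    """Base class for all chemocal errors."""


class InvalidParameterError(ChemocalError, ValueError):
    """A parameter is outside its admissible range."""


class GridError(ChemocalError, ValueError):
    """Wavelength grid is malformed (non-monotone, duplicated, off-grid)."""


class WindowError(ChemocalError, ValueError):
    """A wavelength window selects no columns or lies off the grid."""


class IdMismatchError(ChemocalError, ValueError):
    """Spectra and concentration files disagree on mixture ids."""


class ShapeError(ChemocalError, ValueError):
    """Matrix dimensions are inconsistent."""


class DeflationCollapseError(ChemocalError, ValueError):
    """NIPALS deflation exhausted the rank of X before the requested
    number of latent variables was extracted."""


class TrainingFailureError(ChemocalError, RuntimeError):
    """Levenberg-Marquardt normal equations became numerically singular."""


class ConfigError(ChemocalError, ValueError):
    """A configuration object violates its invariants."""
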