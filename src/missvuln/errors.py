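"""Exception types shared across the package."""


class MissvulnError(Exception):
    """Base class for package-specific errors."""


class ConfigurationError(MissvulnError, ValueError):
    """Invalid configuration (infeasible counts, unknown seed region, ...)."""


class ShapeError(MissvulnError, ValueError):
    """Dimension mismatch between matrices or vectors."""


class AlignmentError(MissvulnError, ValueError):
    """Identifier sets (genes, regions) that should match do not."""


class CorrespondenceError(MissvulnError, ValueError):
    """Invalid region correspondence (e.g. an atlas region mapped twice)."""


class EmptyModelError(MissvulnError, ValueError):
    """No usable features remain for model construction."""
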