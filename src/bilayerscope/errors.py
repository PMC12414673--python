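"""Exception hierarchy shared across the package."""


class BilayerscopeError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(BilayerscopeError, ValueError):
    """A generator specification violates its invariants."""


class PackingError(BilayerscopeError, ValueError):
    """Lipid footprint does not fit the requested box."""


class FormatError(BilayerscopeError, ValueError):
    """A file does not conform to the expected on-disk format."""


class RoleError(BilayerscopeError, KeyError):
    """An analysis requires atom roles that the frame does not carry."""

    def __init__(self, missing, analysis=""):
        if isinstance(missing, str):
            missing = [missing]
        self.missing = list(missing)
        self.analysis = analysis
        what = ", ".join(self.missing)
        suffix = f" (required by {analysis})" if analysis else ""
        super().__init__(f"missing atom role(s): {what}{suffix}")

    def __str__(self):  # KeyError quotes its arg; keep the message readable
        return self.args[0]


class SelectionError(BilayerscopeError, ValueError):
    """An atom/lipid selection is empty or inconsistent."""


class GeometryError(BilayerscopeError, ValueError):
    """Geometric preconditions violated (degenerate points, bad rmax...)."""


class FitError(BilayerscopeError, RuntimeError):
    """A model fit could not be performed."""
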