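"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: :class:`InputError` -> 2,
:class:`NumericalError` -> 3.
"""


class FFDEditError(Exception):
    """Base class for all package errors."""


class InputError(FFDEditError):
    """Invalid or unsupported input (bad file, bad geometry, bad arguments)."""


class GeometryMismatchError(InputError):
    """Two image grids that were required to be identical differ."""


class NumericalError(FFDEditError):
    """Numerical failure: singular lattice frame, rank collapse, parity failure."""
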