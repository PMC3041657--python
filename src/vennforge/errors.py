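"""Exception hierarchy for vennforge.

Every user-facing failure mode maps to a distinct exception class so the
command-line interface can translate each into its own exit code.
"""

from __future__ import annotations


class VennForgeError(Exception):
    """Base class for all vennforge errors."""

    #: exit status used by the CLI for this error family
    exit_code: int = 1


class InvalidInputError(VennForgeError):
    """Malformed user input: negative counts, bad parameters, bad files."""

    exit_code = 6


class UnsupportedSizeError(VennForgeError):
    """More sets than the engine supports (Venn: 4, Euler: 3)."""

    exit_code = 3


class EmptyDiagramError(VennForgeError):
    """Every region of the diagram would be empty."""

    exit_code = 4


class InfeasibleOverlapError(VennForgeError):
    """A requested pairwise intersection area exceeds the smaller circle."""

    exit_code = 7


class UnrealizableArrangementError(VennForgeError):
    """Solved pairwise distances violate the triangle inequality."""

    exit_code = 7


class UnsupportedScalingError(VennForgeError):
    """Area-proportional scaling requested for a case where circle geometry
    is underdetermined (three-set Venn) and therefore disabled."""

    exit_code = 5


class WrongClassError(VennForgeError):
    """A layout routine was handed a diagram class it does not handle."""

    exit_code = 6


class ConfigError(InvalidInputError):
    """Invalid style-configuration value; the message names the key."""

    exit_code = 6


class FormatError(VennForgeError):
    """Unsupported output file format."""

    exit_code = 6
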