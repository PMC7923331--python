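"""Exception hierarchy for mobscan."""


class MobscanError(Exception):
    """Base class for all mobscan errors."""


class FastaFormatError(MobscanError):
    """Malformed FASTA input; message names the offending line."""


class AlphabetError(MobscanError):
    """Sequence contains characters outside the expected alphabet."""


class GeometryError(MobscanError):
    """Incompatible window geometry (e.g. box lengths differing by > 2)."""


class ConfigurationError(MobscanError):
    """Missing or inconsistent configuration (e.g. an empty reference panel)."""


class CoordinateError(MobscanError):
    """A coordinate falls outside the sequence it refers to."""


class PlacementError(MobscanError):
    """Synthetic plants overlap or do not fit the landscape."""


class InputError(MobscanError):
    """Invalid input to an operation (e.g. mixed sequence ids, empty sequence)."""
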