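"""Exception types raised by pbflex."""


class PBFlexError(Exception):
    """Base class for pbflex errors."""


class EnsembleFormatError(PBFlexError):
    """A coordinate file violates the multi-model contract."""


class GeometryError(PBFlexError):
    """A geometric computation is impossible (e.g. missing backbone atom)."""


class SelectionError(PBFlexError):
    """An atom/residue selection is empty or invalid."""
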