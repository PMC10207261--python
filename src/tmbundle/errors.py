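"""Exception hierarchy shared by all tmbundle modules."""


class TMBundleError(Exception):
    """Base class for all tmbundle errors."""


class StructureParseError(TMBundleError):
    """A structure or trajectory file could not be parsed."""


class EmptyInputError(TMBundleError):
    """An input contained no usable records (e.g. a PDB with zero atoms)."""


class SelectionError(TMBundleError):
    """An atom selection could not be resolved or resolved to nothing."""


class GeometryError(TMBundleError):
    """Ill-conditioned or inconsistent geometric input."""


class CorrespondenceError(TMBundleError):
    """Two structures do not share the atom correspondence an operation needs."""


class ConfigError(TMBundleError):
    """Invalid configuration value or file."""
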