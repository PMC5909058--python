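"""Exception hierarchy.

Every library-specific failure derives from :class:`ExdirError`; most also
derive from the closest builtin so that h5py-style code catching e.g.
``KeyError`` or ``FileExistsError`` keeps working.
"""


class ExdirError(Exception):
    """Base class for all errors raised by exdirkit."""


class NotExdirDirectoryError(ExdirError, OSError):
    """A directory that was expected to hold an ``exdir.yaml`` does not."""


class TypeMismatchError(ExdirError, TypeError):
    """An object on disk has a different type than the operation requires."""


class InvalidNameError(ExdirError, ValueError):
    """A proposed object name was rejected by the active validation policy."""


class ObjectExistsError(ExdirError, FileExistsError):
    """Creation would overwrite an existing object."""


class ReadOnlyError(ExdirError, PermissionError):
    """A mutating operation was attempted on a read-only handle."""


class StaleHandleError(ExdirError, RuntimeError):
    """The object behind this handle has been deleted from disk."""


class UnsupportedValueError(ExdirError, TypeError):
    """A value cannot be represented in the restricted YAML subset or NPY."""


class UnsupportedDtypeError(UnsupportedValueError):
    """An array dtype (e.g. object) cannot be stored in the NPY format."""


class NotNpyError(ExdirError, OSError):
    """A file expected to be NPY has a bad magic string or version."""


class CorruptDatasetError(ExdirError, OSError):
    """data.npy payload is shorter than its header declares."""


class YamlParseError(ExdirError, ValueError):
    """Malformed YAML that even lenient reading cannot accept."""

    def __init__(self, message: str, line: int | None = None, column: int | None = None):
        super().__init__(message)
        self.line = line
        self.column = column


class InvalidDocumentError(ExdirError, ValueError):
    """Top-level YAML value is not a mapping (or empty)."""


class MissingPluginError(ExdirError, KeyError):
    """Stored metadata references a plugin that is not registered."""
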