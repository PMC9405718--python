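"""Exception hierarchy."""


class OsteoromError(Exception):
    """Base class for all package errors."""


class MeshError(OsteoromError):
    """Invalid mesh for the requested operation (e.g. not watertight)."""


class MeshParseError(MeshError):
    """File could not be parsed as the named mesh format."""


class PoseLimitError(OsteoromError):
    """An Euler pose lies outside the hard or per-joint rotation limits."""


class GridError(OsteoromError):
    """Invalid sampling-grid specification (step/range mismatch)."""


class DegenerateGeometryError(OsteoromError):
    """Geometric precondition violated (coplanar points, bad ACS, ...)."""
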