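"""Exception types shared across the package."""


class HiprelaxError(Exception):
    """Base class for all package-specific errors."""


class InputError(HiprelaxError, ValueError):
    """Invalid user input: shape mismatches, bad preparation-time grids, out-of-range
    indices, unmatched subject lists, malformed sidecars."""


class EmptyDataError(HiprelaxError, ValueError):
    """An operation received no usable data (empty mask, empty join, no tested voxels)."""
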