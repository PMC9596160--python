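"""Exception types shared across arborquant modules."""


class ConfigError(ValueError):
    """A spec, grid, or parameter value violates its contract."""


class EmptyProfileError(ValueError):
    """An orientation profile with zero total signal cannot be normalized."""


class PathOutOfBoundsError(ValueError):
    """A traced path leaves the image domain; carries the offending vertex."""

    def __init__(self, vertex_index: int, vertex, shape):
        self.vertex_index = vertex_index
        self.vertex = tuple(vertex)
        super().__init__(
            f"path vertex {vertex_index} at (x={self.vertex[0]:.2f}, "
            f"y={self.vertex[1]:.2f}) px lies outside image of shape {shape}"
        )
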