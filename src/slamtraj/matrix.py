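"""Layered gene x cell count matrix, the interchange object of the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

REQUIRED_LAYERS = ("nascent", "old", "total")


@dataclass
class LayeredCountMatrix:
    """Gene x cell matrices under named layers ("nascent", "old", "total").

    Invariant: nascent + old == total elementwise and all entries are
    non-negative. Layers are dense float arrays of shape
    (len(genes), len(cells)); integer content is preserved exactly within
    float64.
    """

    genes: list[str]
    cells: list[str]
    layers: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n_g, n_c = len(self.genes), len(self.cells)
        for name, layer in self.layers.items():
            layer = np.asarray(layer, dtype=float)
            if layer.shape != (n_g, n_c):
                raise ValueError(
                    f"layer {name!r} has shape {layer.shape}, expected {(n_g, n_c)}"
                )
            if np.any(layer < 0):
                raise ValueError(f"layer {name!r} contains negative entries")
            self.layers[name] = layer
        if all(k in self.layers for k in REQUIRED_LAYERS):
            if not np.allclose(
                self.layers["nascent"] + self.layers["old"], self.layers["total"]
            ):
                raise ValueError("nascent + old != total")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def layer(self, name: str) -> np.ndarray:
        try:
            return self.layers[name]
        except KeyError:
            raise KeyError(
                f"unknown layer {name!r}; available: {sorted(self.layers)}"
            ) from None

    def subset_cells(self, keep: np.ndarray | list) -> "LayeredCountMatrix":
        """Return a copy restricted to the given cell indices/boolean mask."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        cells = [self.cells[i] for i in keep]
        layers = {k: v[:, keep].copy() for k, v in self.layers.items()}
        return LayeredCountMatrix(genes=list(self.genes), cells=cells, layers=layers)

    def subset_genes(self, keep: np.ndarray | list) -> "LayeredCountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        genes = [self.genes[i] for i in keep]
        layers = {k: v[keep, :].copy() for k, v in self.layers.items()}
        return LayeredCountMatrix(genes=genes, cells=list(self.cells), layers=layers)
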