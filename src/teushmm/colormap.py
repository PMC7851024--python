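"""Log-odds colormap rendering for biopsy-targeting overlays.

Each ROI grid cell is colored by its normalized log-odds: malignant-
leaning cells (negative log-odds, i.e. the malignant model is the more
likely generator) render in orange/red, benign-leaning cells in blue,
and low-confidence cells near zero in the green/yellow middle of a
diverging palette.  Cells without a prediction render neutral gray.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import matplotlib
import numpy as np
from PIL import Image

from .classify import Prediction
from .errors import ValidationError
from .evaluate import normalize_log_or

_GRAY = (128, 128, 128)


@dataclass(frozen=True)
class ColormapLayout:
    """Mapping ``roi_id -> (row, column)`` grid cell plus pixel size."""

    cells: dict = field(default_factory=dict)
    cell_px: int = 16

    def __post_init__(self) -> None:
        if self.cell_px < 1:
            raise ValidationError("cell_px must be >= 1")
        for roi_id, (r, c) in self.cells.items():
            if r < 0 or c < 0:
                raise ValidationError(f"cell for {roi_id!r} out of grid bounds")

    @property
    def shape(self) -> tuple[int, int]:
        rows = 1 + max((r for r, _ in self.cells.values()), default=0)
        cols = 1 + max((c for _, c in self.cells.values()), default=0)
        return rows, cols


def grid_layout(roi_ids: list[str], n_cols: int | None = None, cell_px: int = 16) -> ColormapLayout:
    """Arrange ROIs row-major on a near-square grid, in the given order."""
    n = len(roi_ids)
    if n == 0:
        raise ValidationError("no ROIs to lay out")
    if len(set(roi_ids)) != n:
        raise ValidationError("roi ids must be unique")
    if n_cols is None:
        n_cols = int(np.ceil(np.sqrt(n)))
    cells = {rid: (i // n_cols, i % n_cols) for i, rid in enumerate(roi_ids)}
    return ColormapLayout(cells=cells, cell_px=cell_px)


def render_colormap(
    predictions: list[Prediction], layout: ColormapLayout, path
) -> None:
    """Render predictions as a PNG heat map of the ROI grid.

    Log-odds are normalized over the rendered frame
    (:func:`~teushmm.evaluate.normalize_log_or`), then mapped through a
    diverging red-yellow-blue palette with the neutral color at 0.5:
    benign-leaning toward blue, malignant-leaning toward red.
    """
    for p in predictions:
        if p.roi_id not in layout.cells:
            raise ValidationError(f"prediction for unknown roi_id {p.roi_id!r}")
    rows, cols = layout.shape
    img = np.empty((rows, cols, 3), dtype=np.uint8)
    img[:] = _GRAY
    if predictions:
        scores = normalize_log_or(np.array([p.log_odds for p in predictions]))
        cmap = matplotlib.colormaps["RdYlBu"]
        for p, s in zip(predictions, scores):
            r, c = layout.cells[p.roi_id]
            rgba = cmap(float(s))
            img[r, c] = [int(round(255 * v)) for v in rgba[:3]]
    big = np.kron(img, np.ones((layout.cell_px, layout.cell_px, 1), dtype=np.uint8))
    Image.fromarray(big, mode="RGB").save(path, format="PNG")
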