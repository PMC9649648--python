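"""Color palette of the synthetic trichrome-like stain.

The synthetic slides emulate a Masson-type connective-tissue stain:
cytoplasm renders pink-beige, collagen in a clearly separated blue-green
hue (so color deconvolution has signal), inflammatory nuclei dark purple,
macrovesicular fat vacuoles near-white, and ballooned hepatocytes as pale
rarefied cells with a central dark nucleus.
"""

from __future__ import annotations

import numpy as np

TISSUE = np.array([232, 178, 190], dtype=np.float64)
VACUOLE = np.array([247, 246, 248], dtype=np.float64)
COLLAGEN = np.array([70, 140, 150], dtype=np.float64)
INFLAMMATORY = np.array([90, 60, 130], dtype=np.float64)
BALLOON_CYTOPLASM = np.array([242, 228, 238], dtype=np.float64)
NUCLEUS = np.array([70, 45, 95], dtype=np.float64)
GLASS = np.array([249, 249, 249], dtype=np.float64)
PEN_MARK = np.array([40, 45, 130], dtype=np.float64)


def optical_density(rgb: np.ndarray) -> np.ndarray:
    """Beer-Lambert optical density per channel: -log10((I + 1) / 256).

    8-bit input is computed in float32 (a lookup-scale quantity; the
    quantization error of the 8-bit image dwarfs float32 rounding); float
    input is kept at its own precision.
    """
    arr = np.asarray(rgb)
    if arr.dtype == np.uint8:
        arr = arr.astype(np.float32)
        arr += 1.0
        arr /= 256.0
        return -np.log10(arr)
    arr = arr.astype(np.float64)
    return -np.log10((arr + 1.0) / 256.0)


def stain_vector(rgb: np.ndarray) -> np.ndarray:
    """Unit-norm optical-density triplet of a pure stain color."""
    od = optical_density(rgb)
    return od / np.linalg.norm(od)
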