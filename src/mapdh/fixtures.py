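"""Synthetic test inputs with machine-readable ground truth.

Every fixture is generated programmatically from a seed: a four-color
355x355 pixel-art image whose 15x15 binned decomposition is known by
construction, noisy micrographs of squares with known sizes, and a
swelling time-lapse produced directly from the saturating-exponential
law. Each generator returns (or writes) a manifest describing the ground
truth so quantification output can be checked against it.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import UnknownFixtureError
from .micrograph import MicrographStack

__all__ = [
    "make_fixture",
    "square_micrograph_stack",
    "swelling_timelapse",
    "watermelon_image",
]

#: RGB palette of the four-color test image (flesh, inner rind, outer
#: rind, background) — chosen well separated in RGB space.
WATERMELON_PALETTE = [
    (220, 60, 50),    # red flesh
    (150, 210, 100),  # light green
    (30, 100, 40),    # dark green
    (235, 170, 190),  # pink background
]


def watermelon_image(
    size: int = 355, n: int = 15, seed: int = 0
) -> tuple[np.ndarray, dict]:
    """A watermelon-style four-color pixel-art image with known structure.

    A 15x15 truth grid of concentric color rings is upsampled to
    ``size x size`` with the same block tiling the binner uses (remainder
    pixels folded into the last row/column), so binning recovers the
    truth grid exactly and clustering recovers the four-color partition.

    Returns ``(image, manifest)`` where the manifest holds the truth
    assignment grid, palette, and per-color cell counts.
    """
    del seed  # image is deterministic; parameter kept for a uniform API
    center = (n - 1) / 2.0
    truth = np.empty((n, n), dtype=np.intp)
    for i in range(n):
        for j in range(n):
            r = float(np.hypot(i - center, j - center))
            if r <= 0.25 * n:
                truth[i, j] = 0
            elif r <= 0.37 * n:
                truth[i, j] = 1
            elif r <= 0.48 * n:
                truth[i, j] = 2
            else:
                truth[i, j] = 3
    block = size // n
    idx = np.minimum(np.arange(size) // block, n - 1)
    palette = np.asarray(WATERMELON_PALETTE, dtype=np.uint8)
    img = palette[truth[idx[:, None], idx[None, :]]]
    manifest = {
        "size": size,
        "n": n,
        "palette": [list(c) for c in WATERMELON_PALETTE],
        "assignment": truth.tolist(),
        "cell_counts": np.bincount(truth.ravel(), minlength=4).tolist(),
    }
    return img, manifest


def square_micrograph_stack(
    sizes_um: tuple[float, ...] = (50.0, 30.0, 20.0),
    pixel_size_um: float = 1.0,
    background: float = 100.0,
    foreground: float = 600.0,
    noise_sigma: float = 5.0,
    seed: int = 0,
) -> tuple[MicrographStack, dict]:
    """One noisy single-channel micrograph of bright squares of known sizes.

    Squares are laid out along a row with generous spacing. The manifest
    records each square's size and center in pixels.
    """
    rng = np.random.default_rng(seed)
    gap = 40
    h_px = int(max(sizes_um) / pixel_size_um) + 2 * gap
    widths = [int(round(s / pixel_size_um)) for s in sizes_um]
    w_px = sum(widths) + gap * (len(sizes_um) + 1)
    img = np.full((h_px, w_px), background, dtype=np.float64)
    centers = []
    x = gap
    for wpx in widths:
        r0 = (h_px - wpx) // 2
        img[r0:r0 + wpx, x:x + wpx] = foreground
        centers.append([r0 + wpx / 2.0, x + wpx / 2.0])
        x += wpx + gap
    img = np.clip(img + rng.normal(0, noise_sigma, img.shape), 0, None)
    stack = MicrographStack(
        channels={"Cy3": img}, pixel_size_um=pixel_size_um,
        meta={"fixture": "squares"},
    )
    manifest = {
        "sizes_um": list(sizes_um),
        "pixel_size_um": pixel_size_um,
        "centers_px": centers,
        "background": background,
        "foreground": foreground,
        "noise_sigma": noise_sigma,
    }
    return stack, manifest


def swelling_timelapse(
    L0_um: float = 200.0,
    amplitude: float = 0.51,
    tau_h: float = 8.0,
    hours: tuple[float, ...] = (0.0, 6.0, 12.0, 24.0, 36.0, 48.0, 60.0),
    pixel_size_um: float = 1.0,
    background: float = 100.0,
    foreground: float = 600.0,
    noise_sigma: float = 5.0,
    seed: int = 0,
) -> tuple[list[MicrographStack], dict]:
    """Time-lapse of one square growing by the saturating-exponential law.

    Constructed geometrically (independent of the virtual instrument):
    at time t the square's side is ``L0 * (1 + A * (1 - exp(-t/tau)))``.
    The manifest carries the exact expected dL/L0 series.
    """
    rng = np.random.default_rng(seed)
    field = int(np.ceil(L0_um * (1 + amplitude) / pixel_size_um)) + 80
    stacks = []
    truth = []
    for t in hours:
        L = L0_um * (1.0 + amplitude * (1.0 - np.exp(-t / tau_h)))
        truth.append((L - L0_um) / L0_um)
        side = int(round(L / pixel_size_um))
        img = np.full((field, field), background, dtype=np.float64)
        r0 = (field - side) // 2
        img[r0:r0 + side, r0:r0 + side] = foreground
        img = np.clip(img + rng.normal(0, noise_sigma, img.shape), 0, None)
        stacks.append(MicrographStack(
            channels={"Cy3": img}, pixel_size_um=pixel_size_um, time_h=float(t),
            meta={"fixture": "swelling"},
        ))
    manifest = {
        "L0_um": L0_um,
        "amplitude": amplitude,
        "tau_h": tau_h,
        "hours": list(hours),
        "expected_dL_over_L0": truth,
        "pixel_size_um": pixel_size_um,
    }
    return stacks, manifest


def make_fixture(name: str, seed: int, outdir: str | Path) -> dict:
    """Write a named fixture package (data files + manifest.json) to disk."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if name == "watermelon":
        img, manifest = watermelon_image(seed=seed)
        Image.fromarray(img).save(out / "watermelon.png")
        files = ["watermelon.png"]
    elif name == "squares":
        stack, manifest = square_micrograph_stack(seed=seed)
        stack.save_tiff(out / "squares.tif")
        files = ["squares.tif"]
    elif name == "swelling":
        stacks, manifest = swelling_timelapse(seed=seed)
        files = []
        for i, s in enumerate(stacks):
            fname = f"swelling_t{int(s.time_h):03d}h.tif"
            s.save_tiff(out / fname)
            files.append(fname)
    else:
        raise UnknownFixtureError(name)
    manifest = {"fixture": name, "seed": seed, "files": files, **manifest}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
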