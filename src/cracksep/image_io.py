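"""Reading preprocessed images and indexing the two-level dataset tree.

Input images are 8-bit single-channel TIFF or JPEG files whose filename ends
in a three-digit threshold suffix, e.g. ``sample_1_162thld.tif``: the digits
before ``thld`` are the intensity threshold to use when segmenting that
image.  A dataset is a root directory ("updir") containing one subdirectory
per sample series (mutant, growth condition, ...), each holding the series'
images.  Nesting deeper than one level is not traversed.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image as PILImage

from .errors import EmptyDatasetError, NamingConventionError, UnsupportedImageError

logger = logging.getLogger(__name__)

#: Accepted file extensions (lower-case).
IMAGE_EXTENSIONS = (".tif", ".tiff", ".jpg", ".jpeg")

_THRESHOLD_RE = re.compile(r"^.*_(\d{3})thld$")


@dataclass(frozen=True)
class IntensityImage:
    """A 2D 8-bit grayscale image with a physical pixel size.

    Parameters
    ----------
    pixels
        2D ``uint8`` array, row-major (row 0 is the top of the displayed
        image).
    pixel_size
        Physical edge length of one pixel in micrometres; strictly positive.
    source_path
        Provenance string (file path or synthetic-scene identifier).
    """

    pixels: np.ndarray
    pixel_size: float = 1.0
    source_path: str = "<memory>"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise UnsupportedImageError(
                f"{self.source_path}: expected a non-empty 2D pixel grid, "
                f"got shape {px.shape}"
            )
        if px.dtype != np.uint8:
            raise UnsupportedImageError(
                f"{self.source_path}: expected 8-bit intensities, got dtype {px.dtype}"
            )
        if not self.pixel_size > 0:
            raise UnsupportedImageError(
                f"{self.source_path}: pixel_size must be > 0 µm, got {self.pixel_size}"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class ImageEntry:
    """One indexed dataset image: its path and the filename-encoded threshold."""

    path: Path
    threshold: int


@dataclass(frozen=True)
class DatasetIndex:
    """Index of a dataset root: ordered mapping series name -> image entries."""

    root: Path
    series: dict[str, list[ImageEntry]] = field(default_factory=dict)

    @property
    def n_images(self) -> int:
        return sum(len(entries) for entries in self.series.values())


def parse_threshold_from_filename(filename: str) -> int:
    """Parse the segmentation threshold encoded in an image filename.

    The stem must end in ``_XXXthld`` where ``XXX`` is exactly three digits;
    e.g. ``sample_1_162thld.tif`` -> 162.  The three-digit requirement is
    strict: ``a_05thld.tif`` and ``a_1624thld.tif`` are both rejected.
    """
    name = Path(filename).name
    suffix = Path(name).suffix.lower()
    if suffix not in IMAGE_EXTENSIONS:
        raise NamingConventionError(
            f"{filename!r}: extension {suffix!r} not one of {IMAGE_EXTENSIONS}"
        )
    stem = Path(name).stem
    m = _THRESHOLD_RE.match(stem)
    if m is None:
        raise NamingConventionError(
            f"{filename!r} does not match the required naming convention "
            "'<name>_XXXthld.<ext>' with XXX exactly three digits "
            "(e.g. 'sample_1_162thld.tif')"
        )
    return int(m.group(1))


def load_grayscale_image(path: str | Path, pixel_size: float = 1.0) -> IntensityImage:
    """Load a preprocessed 8-bit grayscale TIFF or JPEG.

    Pixel values of 8-bit TIFF input are preserved bit-exactly.  Multi-channel
    or non-8-bit files raise :class:`UnsupportedImageError`: preprocessing
    (8-bit conversion, channel splitting) is the user's responsibility and a
    silent conversion would change the threshold semantics.
    """
    path = Path(path)
    ext = path.suffix.lower()
    if ext not in IMAGE_EXTENSIONS:
        raise UnsupportedImageError(
            f"{path}: extension {ext!r} not one of {IMAGE_EXTENSIONS}"
        )
    try:
        if ext in (".tif", ".tiff"):
            pixels = tifffile.imread(path)
        else:
            with PILImage.open(path) as im:
                if im.mode != "L":
                    raise UnsupportedImageError(
                        f"{path}: JPEG mode {im.mode!r} is not 8-bit grayscale; "
                        "preprocess the image (convert to 8-bit, single channel) "
                        "before analysis"
                    )
                pixels = np.asarray(im)
    except (OSError, ValueError) as exc:
        if isinstance(exc, UnsupportedImageError):
            raise
        raise CrackSepIOError(f"cannot read image file {path}: {exc}") from exc

    pixels = np.asarray(pixels)
    if pixels.ndim != 2:
        raise UnsupportedImageError(
            f"{path}: expected a single-channel 2D image, got shape "
            f"{pixels.shape}; preprocess the image (split channels) before analysis"
        )
    if pixels.dtype != np.uint8:
        raise UnsupportedImageError(
            f"{path}: expected 8-bit pixel data, got dtype {pixels.dtype}; "
            "convert the image to 8-bit before analysis"
        )
    return IntensityImage(pixels=pixels, pixel_size=pixel_size, source_path=str(path))


class CrackSepIOError(OSError):
    """Unreadable or unwritable file, with the offending path in the message."""


def save_grayscale_tiff(image: IntensityImage, path: str | Path) -> Path:
    """Write an 8-bit single-channel TIFF; load -> save -> load is bit-exact."""
    path = Path(path)
    tifffile.imwrite(path, image.pixels)
    return path


def scan_dataset(root: str | Path) -> DatasetIndex:
    """Index a dataset root directory.

    Every immediate subdirectory of ``root`` becomes a series; every file in
    it that matches the naming convention is indexed with its parsed
    threshold.  Non-conforming files are skipped with a logged warning.
    Series and images are ordered lexicographically, so repeated scans of an
    unchanged tree produce identical indexes.
    """
    root = Path(root)
    if not root.is_dir():
        raise CrackSepIOError(f"dataset root {root} does not exist or is not a directory")

    series: dict[str, list[ImageEntry]] = {}
    for subdir in sorted(p for p in root.iterdir() if p.is_dir()):
        entries: list[ImageEntry] = []
        for f in sorted(p for p in subdir.iterdir() if p.is_file()):
            if f.suffix.lower() not in IMAGE_EXTENSIONS:
                logger.warning("ignoring non-image file %s", f)
                continue
            try:
                threshold = parse_threshold_from_filename(f.name)
            except NamingConventionError:
                logger.warning(
                    "ignoring image file %s: name does not match '<name>_XXXthld.<ext>'", f
                )
                continue
            entries.append(ImageEntry(path=f, threshold=threshold))
        if entries:
            series[subdir.name] = entries

    if not series:
        raise EmptyDatasetError(
            f"dataset root {root} has no subdirectory containing a conforming "
            "image ('<name>_XXXthld.tif/.jpg')"
        )
    return DatasetIndex(root=root, series=series)
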