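"""Core containers and text I/O for Hi-C contact matrices and 3D structures.

A contact map is a square, symmetric matrix of non-negative integer
*contact counts*: entry ``c[i, j]`` is the number of times genomic bins
(*beads*) ``i`` and ``j`` were observed ligated together.  A 3D structure
is one point in Euclidean space per bead.  Both carry per-bead chromosome
and within-chromosome bin annotations so that multi-chromosome maps can
distinguish intra- from inter-chromosomal bead pairs.

Formats are deliberately plain text:

* dense  — whitespace-delimited ``n x n`` matrix;
* coo    — one ``i <TAB> j <TAB> count`` triplet per line, 0-based global
  bin indices, ``#`` comments allowed, only ``i < j`` entries required;
* structure — one ``chrom bin_index x y z`` line per bead, with the
  literal token ``NA`` marking beads without coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ContactMatrix",
    "Structure3D",
    "InputError",
    "read_counts",
    "write_counts",
    "read_structure",
    "write_structure",
]


class InputError(ValueError):
    """Raised when an input file or in-memory object violates the format contract."""


def _default_annotations(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.array(["chr1"] * n, dtype=object), np.arange(n)


@dataclass
class ContactMatrix:
    """Square symmetric integer contact-count matrix with bead annotations.

    Parameters
    ----------
    counts
        ``(n, n)`` array of non-negative integers.  Symmetrised and
        diagonal-zeroed on construction (self-contacts carry no distance
        information under a power-law count-to-distance map).
    chrom, bin_index
        Per-bead chromosome label and 0-based index within its chromosome.
        Default: a single chromosome ``chr1`` with consecutive bins.
    resolution
        Bin size in base pairs; informational only.
    """

    counts: np.ndarray
    chrom: np.ndarray = None
    bin_index: np.ndarray = None
    resolution: int = 1

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise InputError(f"counts must be square, got shape {c.shape}")
        if not np.all(np.isfinite(c)):
            raise InputError("counts contain non-finite values")
        if np.any(c < 0):
            raise InputError("counts must be non-negative")
        if not np.all(c == np.round(c)):
            raise InputError("counts must be integral")
        asym = np.argwhere(c != c.T)
        if asym.size:
            i, j = asym[0]
            raise InputError(
                f"count matrix is asymmetric: c[{i},{j}]={c[i, j]} != c[{j},{i}]={c[j, i]}"
            )
        c = c.astype(np.int64)
        if np.any(np.diag(c) != 0):
            logger.warning("nonzero diagonal counts found; zeroing the diagonal")
            np.fill_diagonal(c, 0)
        self.counts = c
        n = c.shape[0]
        if self.chrom is None or self.bin_index is None:
            ch, bi = _default_annotations(n)
            self.chrom = ch if self.chrom is None else np.asarray(self.chrom, dtype=object)
            self.bin_index = bi if self.bin_index is None else np.asarray(self.bin_index)
        else:
            self.chrom = np.asarray(self.chrom, dtype=object)
            self.bin_index = np.asarray(self.bin_index)
        if len(self.chrom) != n or len(self.bin_index) != n:
            raise InputError("annotation length does not match matrix size")

    @property
    def n(self) -> int:
        return self.counts.shape[0]

    def marginal(self) -> np.ndarray:
        """Per-bead total contact count (row sum)."""
        return self.counts.sum(axis=1)

    def intra_mask(self) -> np.ndarray:
        """``(n, n)`` boolean mask of intra-chromosomal bead pairs."""
        return self.chrom[:, None] == self.chrom[None, :]


@dataclass
class Structure3D:
    """3D bead coordinates with a validity mask.

    Invalid beads (``valid_mask`` False) hold NaN coordinates and are
    excluded from every distance computation.  Coordinates are stored as
    an ``(n, 3)`` array in arbitrary length units; the inference is only
    defined up to rotation, translation and overall scale.
    """

    coords: np.ndarray
    valid_mask: np.ndarray = None
    chrom: np.ndarray = None
    bin_index: np.ndarray = None

    def __post_init__(self) -> None:
        x = np.asarray(self.coords, dtype=float)
        if x.ndim != 2 or x.shape[1] != 3:
            raise InputError(f"coords must have shape (n, 3), got {x.shape}")
        n = x.shape[0]
        if self.valid_mask is None:
            self.valid_mask = np.all(np.isfinite(x), axis=1)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != (n,):
                raise InputError("valid_mask length does not match bead count")
        x = x.copy()
        x[~self.valid_mask] = np.nan
        self.coords = x
        if self.chrom is None or self.bin_index is None:
            ch, bi = _default_annotations(n)
            self.chrom = ch if self.chrom is None else np.asarray(self.chrom, dtype=object)
            self.bin_index = bi if self.bin_index is None else np.asarray(self.bin_index)
        else:
            self.chrom = np.asarray(self.chrom, dtype=object)
            self.bin_index = np.asarray(self.bin_index)

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    def pairwise_distances(self) -> np.ndarray:
        """Full ``(n, n)`` Euclidean distance matrix; NaN where a bead is invalid."""
        diff = self.coords[:, None, :] - self.coords[None, :, :]
        return np.sqrt((diff**2).sum(axis=-1))

    def copy(self) -> "Structure3D":
        return Structure3D(
            self.coords.copy(),
            self.valid_mask.copy(),
            self.chrom.copy(),
            self.bin_index.copy(),
        )


# ---------------------------------------------------------------------------
# contact-count I/O


def _read_bins(path) -> tuple[np.ndarray, np.ndarray, int]:
    """Sidecar bin table: ``chrom <TAB> bin_index [resolution]`` per line."""
    chroms, bins, resolution = [], [], 1
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            chroms.append(parts[0])
            bins.append(int(parts[1]))
            if len(parts) > 2:
                resolution = int(parts[2])
    return np.array(chroms, dtype=object), np.array(bins), resolution


def read_counts(path, format: str = "dense", *, n: int | None = None, bins=None) -> ContactMatrix:
    """Read a contact matrix from ``dense`` or ``coo`` text.

    COO triplets may list each pair once in either orientation; listing
    both ``(i, j)`` and ``(j, i)`` is accepted only when the values agree.
    Absent pairs are zero.  ``n`` fixes the matrix size for COO input
    (otherwise the largest index + 1 is used); ``bins`` names an optional
    sidecar bin table supplying chrom/bin_index/resolution.
    """
    chrom = bin_index = None
    resolution = 1
    if bins is not None:
        chrom, bin_index, resolution = _read_bins(bins)
        if n is None:
            n = len(chrom)

    if format == "dense":
        try:
            c = np.loadtxt(path, ndmin=2)
        except ValueError as exc:
            raise InputError(f"malformed dense matrix in {path}: {exc}") from None
        return ContactMatrix(c, chrom, bin_index, resolution)

    if format != "coo":
        raise InputError(f"unknown format {format!r}; expected 'dense' or 'coo'")

    entries: dict[tuple[int, int], float] = {}
    max_idx = -1
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise InputError(f"{path}:{lineno}: expected 'i j count', got {line!r}")
            try:
                i, j = int(parts[0]), int(parts[1])
                v = float(parts[2])
            except ValueError:
                raise InputError(f"{path}:{lineno}: non-numeric field in {line!r}") from None
            if v < 0 or v != round(v):
                raise InputError(f"{path}:{lineno}: count must be a non-negative integer, got {v}")
            if i < 0 or j < 0:
                raise InputError(f"{path}:{lineno}: negative bin index")
            if n is not None and (i >= n or j >= n):
                raise InputError(f"{path}:{lineno}: bin index out of range for n={n}")
            key = (min(i, j), max(i, j))
            if key in entries and entries[key] != v:
                raise InputError(
                    f"{path}:{lineno}: conflicting duplicate entry for pair {key}: "
                    f"{entries[key]} vs {v}"
                )
            entries[key] = v
            max_idx = max(max_idx, i, j)

    size = n if n is not None else max_idx + 1
    if size <= 0:
        raise InputError(f"{path}: no entries and no explicit size")
    c = np.zeros((size, size))
    for (i, j), v in entries.items():
        c[i, j] = v
        c[j, i] = v
    return ContactMatrix(c, chrom, bin_index, resolution)


def write_counts(m: ContactMatrix, path, format: str = "dense") -> None:
    """Write a contact matrix; ``read_counts`` round-trips it exactly."""
    if format == "dense":
        np.savetxt(path, m.counts, fmt="%d")
    elif format == "coo":
        iu, ju = np.triu_indices(m.n, k=1)
        nz = m.counts[iu, ju] > 0
        with open(path, "w") as fh:
            fh.write(f"# n={m.n}\n# i\tj\tcount\n")
            for i, j, v in zip(iu[nz], ju[nz], m.counts[iu, ju][nz]):
                fh.write(f"{i}\t{j}\t{v}\n")
    else:
        raise InputError(f"unknown format {format!r}; expected 'dense' or 'coo'")


# ---------------------------------------------------------------------------
# structure I/O

_NA = "NA"


def read_structure(path) -> Structure3D:
    """Read a ``chrom bin_index x y z`` table; ``NA`` coordinates mark invalid beads."""
    chroms, bins, coords, valid = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 5:
                raise InputError(f"{path}:{lineno}: expected 5 columns, got {len(parts)}")
            chroms.append(parts[0])
            try:
                bins.append(int(parts[1]))
            except ValueError:
                raise InputError(f"{path}:{lineno}: bad bin index {parts[1]!r}") from None
            if all(p == _NA for p in parts[2:]):
                coords.append((np.nan, np.nan, np.nan))
                valid.append(False)
            else:
                try:
                    coords.append(tuple(float(p) for p in parts[2:]))
                except ValueError:
                    raise InputError(f"{path}:{lineno}: bad coordinate in {line!r}") from None
                valid.append(True)
    if not coords:
        raise InputError(f"{path}: empty structure file")
    return Structure3D(
        np.array(coords),
        np.array(valid),
        np.array(chroms, dtype=object),
        np.array(bins),
    )


def write_structure(s: Structure3D, path) -> None:
    """Write a structure; round trip preserves coordinates to full precision."""
    with open(path, "w") as fh:
        fh.write("# chrom\tbin\tx\ty\tz\n")
        for k in range(s.n):
            if s.valid_mask[k]:
                x, y, z = (f"{v:.17g}" for v in s.coords[k])
            else:
                x = y = z = _NA
            fh.write(f"{s.chrom[k]}\t{s.bin_index[k]}\t{x}\t{y}\t{z}\n")
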