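"""Spectrum containers and text-format readers/writers.

Two interchange formats are supported:

* **wide-CSV** — first column ``wavenumber`` (cm^-1), one column per sample
  (header row = sample ids).  Metadata travels in a separate delimited table
  keyed by ``sample_id``.
* **JCAMP-like** — a minimal JCAMP-DX dialect: per-spectrum blocks delimited
  by ``##TITLE=<sample_id>`` / ``##END=``, with ``(x, y)`` pairs listed one
  per line under ``##XYDATA=(X,Y)``.  Compression tables of full JCAMP-DX are
  not supported.

Wavenumber grids are stored ascending; descending input is re-ordered on
read.  All region arithmetic in the package uses half-open ``[lo, hi)``
intervals so adjacent windows tile without double counting.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "SpectrumSet",
    "SpectraError",
    "ParseError",
    "GridMismatchError",
    "read_spectra",
    "write_spectra",
    "restrict_region",
    "default_grid",
]


class SpectraError(ValueError):
    """Base class for spectra container/IO errors."""


class ParseError(SpectraError):
    """A file failed validation; the message names the offending record."""


class GridMismatchError(SpectraError):
    """Spectra do not share a wavenumber grid."""


def default_grid(lo: float = 600.0, hi: float = 4000.0, step: float = 2.0) -> np.ndarray:
    """Default instrument grid: 600-4000 cm^-1 at 2 cm^-1 spacing (1701 points)."""
    n = int(round((hi - lo) / step)) + 1
    return lo + step * np.arange(n)


@dataclass
class Spectrum:
    """One absorbance trace on a strictly monotone wavenumber grid."""

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    sample_id: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavenumbers.ndim != 1 or self.absorbance.ndim != 1:
            raise SpectraError(f"spectrum {self.sample_id!r}: arrays must be 1-D")
        if self.wavenumbers.size != self.absorbance.size:
            raise SpectraError(
                f"spectrum {self.sample_id!r}: grid length {self.wavenumbers.size} "
                f"!= absorbance length {self.absorbance.size}"
            )
        if self.wavenumbers.size == 0:
            raise SpectraError(f"spectrum {self.sample_id!r}: empty grid")
        d = np.diff(self.wavenumbers)
        if np.all(d < 0):  # descending input: re-order ascending
            self.wavenumbers = self.wavenumbers[::-1].copy()
            self.absorbance = self.absorbance[::-1].copy()
        elif self.wavenumbers.size > 1 and not np.all(d > 0):
            raise SpectraError(
                f"spectrum {self.sample_id!r}: wavenumbers not strictly monotone"
            )
        if not np.all(np.isfinite(self.absorbance)):
            raise SpectraError(f"spectrum {self.sample_id!r}: non-finite absorbance")

    def __len__(self) -> int:
        return self.wavenumbers.size


class SpectrumSet:
    """An ordered collection of spectra sharing one grid, plus a metadata table.

    Internally a dense ``(n_samples, n_points)`` absorbance matrix; metadata is
    a :class:`pandas.DataFrame` indexed by ``sample_id``.
    """

    def __init__(
        self,
        wavenumbers: np.ndarray,
        absorbance: np.ndarray,
        sample_ids: Iterable[str],
        metadata: pd.DataFrame | None = None,
    ) -> None:
        self.wavenumbers = np.asarray(wavenumbers, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(absorbance, dtype=float))
        self.sample_ids = [str(s) for s in sample_ids]
        if self.wavenumbers.size > 1 and not np.all(np.diff(self.wavenumbers) > 0):
            raise SpectraError("SpectrumSet grid must be strictly ascending")
        if self.absorbance.shape != (len(self.sample_ids), self.wavenumbers.size):
            raise SpectraError(
                f"absorbance shape {self.absorbance.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {self.wavenumbers.size} points"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise SpectraError(f"duplicate sample ids: {dupes}")
        if metadata is None:
            metadata = pd.DataFrame(index=pd.Index(self.sample_ids, name="sample_id"))
        else:
            metadata = metadata.copy()
            if metadata.index.name != "sample_id":
                if "sample_id" in metadata.columns:
                    metadata = metadata.set_index("sample_id")
                else:
                    metadata.index = pd.Index(self.sample_ids, name="sample_id")
            metadata = metadata.loc[self.sample_ids]
        self.metadata = metadata

    @classmethod
    def from_spectra(cls, spectra: Iterable[Spectrum]) -> "SpectrumSet":
        spectra = list(spectra)
        if not spectra:
            raise SpectraError("cannot build a SpectrumSet from zero spectra")
        grid = spectra[0].wavenumbers
        for sp in spectra[1:]:
            if sp.wavenumbers.shape != grid.shape or not np.allclose(
                sp.wavenumbers, grid, rtol=0, atol=1e-9
            ):
                raise GridMismatchError(
                    f"spectrum {sp.sample_id!r} is not on the shared grid"
                )
        meta = pd.DataFrame(
            [sp.metadata for sp in spectra],
            index=pd.Index([sp.sample_id for sp in spectra], name="sample_id"),
        )
        return cls(
            grid,
            np.vstack([sp.absorbance for sp in spectra]),
            [sp.sample_id for sp in spectra],
            meta,
        )

    def __len__(self) -> int:
        return len(self.sample_ids)

    def __iter__(self) -> Iterator[Spectrum]:
        for i, sid in enumerate(self.sample_ids):
            row = self.metadata.loc[sid]
            yield Spectrum(
                self.wavenumbers, self.absorbance[i], sid, dict(row.dropna())
            )

    def __getitem__(self, sample_id: str) -> Spectrum:
        i = self.sample_ids.index(sample_id)
        return Spectrum(
            self.wavenumbers,
            self.absorbance[i],
            sample_id,
            dict(self.metadata.loc[sample_id].dropna()),
        )

    def with_absorbance(self, matrix: np.ndarray) -> "SpectrumSet":
        """Copy of the set with a replaced absorbance matrix (same samples/grid)."""
        return SpectrumSet(self.wavenumbers, matrix, self.sample_ids, self.metadata)

    def select(self, sample_ids: Iterable[str]) -> "SpectrumSet":
        ids = [str(s) for s in sample_ids]
        idx = [self.sample_ids.index(s) for s in ids]
        return SpectrumSet(
            self.wavenumbers, self.absorbance[idx], ids, self.metadata.loc[ids]
        )


def restrict_region(sset: SpectrumSet, lo: float, hi: float) -> SpectrumSet:
    """Restrict a set to grid points in the half-open window ``[lo, hi)``."""
    if not lo < hi:
        raise SpectraError(f"need lo < hi, got [{lo}, {hi})")
    mask = (sset.wavenumbers >= lo) & (sset.wavenumbers < hi)
    if not mask.any():
        raise SpectraError(
            f"window [{lo}, {hi}) has no overlap with grid "
            f"[{sset.wavenumbers[0]}, {sset.wavenumbers[-1]}]"
        )
    return SpectrumSet(
        sset.wavenumbers[mask],
        sset.absorbance[:, mask],
        sset.sample_ids,
        sset.metadata,
    )


# ---------------------------------------------------------------- wide CSV

def _write_wide_csv(sset: SpectrumSet, path: str) -> None:
    df = pd.DataFrame(
        sset.absorbance.T, columns=sset.sample_ids
    )
    df.insert(0, "wavenumber", sset.wavenumbers)
    df.to_csv(path, index=False, float_format="%.17g")  # lossless round trip
    meta_path = _metadata_path(path)
    if len(sset.metadata.columns):
        sset.metadata.to_csv(meta_path)


def _metadata_path(path: str) -> str:
    root, ext = os.path.splitext(path)
    return f"{root}.meta{ext or '.csv'}"


def _read_wide_csv(path: str) -> SpectrumSet:
    with open(path) as fh:
        header_line = fh.readline()
        while header_line.startswith("#"):
            header_line = fh.readline()
    raw_ids = [c.strip() for c in header_line.rstrip("\n").split(",")[1:]]
    if len(set(raw_ids)) != len(raw_ids):
        dupes = sorted({s for s in raw_ids if raw_ids.count(s) > 1})
        raise ParseError(f"{path}: duplicate sample ids {dupes}")
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if df.shape[1] < 2:
        raise ParseError(f"{path}: wide-CSV needs a wavenumber column plus >=1 sample")
    if df.columns[0] != "wavenumber":
        raise ParseError(
            f"{path}: first column must be 'wavenumber', got {df.columns[0]!r}"
        )
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise ParseError(f"{path}: ragged/missing values in columns {bad}")
    ids = [str(c) for c in df.columns[1:]]
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise ParseError(f"{path}: duplicate sample ids {dupes}")
    grid = df["wavenumber"].to_numpy(dtype=float)
    mat = df[df.columns[1:]].to_numpy(dtype=float).T
    order_ok = np.all(np.diff(grid) > 0)
    if not order_ok:
        if grid.size > 1 and np.all(np.diff(grid) < 0):
            grid, mat = grid[::-1].copy(), mat[:, ::-1].copy()
        else:
            raise ParseError(f"{path}: wavenumber column not strictly monotone")
    meta_path = _metadata_path(path)
    meta = None
    if os.path.exists(meta_path):
        meta = pd.read_csv(
            meta_path, comment="#", float_precision="round_trip"
        ).set_index("sample_id")
        meta.index = meta.index.astype(str)
    return SpectrumSet(grid, mat, ids, meta)


# ---------------------------------------------------------------- JCAMP-like

def _write_jcamp(sset: SpectrumSet, path: str) -> None:
    with open(path, "w") as fh:
        for sp in sset:
            fh.write(f"##TITLE={sp.sample_id}\n")
            fh.write("##XUNITS=1/CM\n##YUNITS=ABSORBANCE\n")
            for k, v in sp.metadata.items():
                fh.write(f"##${k}={v}\n")
            fh.write("##XYDATA=(X,Y)\n")
            for x, y in zip(sp.wavenumbers, sp.absorbance):
                fh.write(f"{float(x)!r} {float(y)!r}\n")
            fh.write("##END=\n")


def _read_jcamp(path: str) -> SpectrumSet:
    spectra: list[Spectrum] = []
    title: str | None = None
    xs: list[float] = []
    ys: list[float] = []
    meta: dict = {}
    in_data = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("##"):
                key, _, val = line[2:].partition("=")
                key = key.strip().upper()
                in_data = False
                if key == "TITLE":
                    if title is not None:
                        raise ParseError(
                            f"{path}:{lineno}: block {title!r} missing ##END="
                        )
                    title, xs, ys, meta = val.strip(), [], [], {}
                elif key == "XYDATA":
                    in_data = True
                elif key == "END":
                    if title is None:
                        raise ParseError(f"{path}:{lineno}: ##END= outside a block")
                    spectra.append(Spectrum(np.array(xs), np.array(ys), title, meta))
                    title = None
                elif key.startswith("$"):
                    meta[key[1:].lower()] = _coerce(val.strip())
                continue
            if in_data:
                parts = line.replace(",", " ").split()
                if len(parts) != 2:
                    raise ParseError(
                        f"{path}:{lineno}: expected 'x y' pair in block {title!r}"
                    )
                xs.append(float(parts[0]))
                ys.append(float(parts[1]))
    if title is not None:
        raise ParseError(f"{path}: block {title!r} missing ##END=")
    if not spectra:
        raise ParseError(f"{path}: no spectra found")
    return SpectrumSet.from_spectra(spectra)


def _coerce(val: str):
    for cast in (int, float):
        try:
            return cast(val)
        except ValueError:
            pass
    return val


_FORMATS = {"wide-csv", "jcamp-like"}


def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in _FORMATS:
            raise SpectraError(f"unknown format {fmt!r}; choose from {sorted(_FORMATS)}")
        return fmt
    return "jcamp-like" if str(path).endswith((".jdx", ".dx", ".jcamp")) else "wide-csv"


def read_spectra(path: str, format: str | None = None) -> SpectrumSet:
    """Read a :class:`SpectrumSet` from ``path`` (wide-CSV or JCAMP-like)."""
    fmt = _infer_format(path, format)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    return _read_wide_csv(path) if fmt == "wide-csv" else _read_jcamp(path)


def write_spectra(sset: SpectrumSet, path: str, format: str | None = None) -> None:
    """Write a non-empty :class:`SpectrumSet`; lossless round trip with read_spectra."""
    if len(sset) == 0:
        raise SpectraError("refusing to write an empty SpectrumSet")
    fmt = _infer_format(path, format)
    if fmt == "wide-csv":
        _write_wide_csv(sset, path)
    else:
        _write_jcamp(sset, path)
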