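"""HDF5 interchange for cine series, sampling patterns, dictionaries and
phase schedules; optional NIfTI export of magnitude frames for viewers."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .dictionary import CardiacMotionDictionary
from .sampling import KSpaceFrame, SamplingPattern
from .series import CineSeries

__all__ = [
    "save_cine",
    "load_cine",
    "save_patterns",
    "load_patterns",
    "save_kframes",
    "load_kframes",
    "save_dictionary",
    "load_dictionary",
    "export_magnitude_nifti",
]


def save_cine(path: str | Path, series: CineSeries) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("frames", data=series.frames)
        fh.create_dataset("phase_labels", data=series.phase_labels)
        fh.attrs["period_T"] = series.period_T
        fh.attrs["is_training"] = series.is_training
        fh.attrs["pixel_scale"] = series.pixel_scale


def load_cine(path: str | Path) -> CineSeries:
    with h5py.File(path, "r") as fh:
        return CineSeries(
            frames=fh["frames"][...],
            phase_labels=fh["phase_labels"][...],
            period_T=int(fh.attrs["period_T"]),
            is_training=bool(fh.attrs.get("is_training", False)),
            pixel_scale=float(fh.attrs.get("pixel_scale", 1.0)),
        )


def _write_pattern(group: h5py.Group, pat: SamplingPattern) -> None:
    group.attrs["kind"] = pat.kind
    group.attrs["N"] = pat.N
    group.attrs["n_lines_or_spokes"] = pat.n_lines_or_spokes
    group.attrs["samples_per_line"] = pat.samples_per_line
    group.attrs["per_frame_variation"] = pat.per_frame_variation
    group.attrs["frame_index"] = pat.frame_index
    if pat.kind == "cartesian":
        group.create_dataset("mask", data=pat.mask)
    else:
        group.create_dataset("trajectory", data=pat.trajectory)


def _read_pattern(group: h5py.Group) -> SamplingPattern:
    kind = group.attrs["kind"]
    return SamplingPattern(
        kind=kind,
        N=int(group.attrs["N"]),
        mask=group["mask"][...] if kind == "cartesian" else None,
        trajectory=group["trajectory"][...] if kind != "cartesian" else None,
        n_lines_or_spokes=int(group.attrs["n_lines_or_spokes"]),
        samples_per_line=int(group.attrs["samples_per_line"]),
        per_frame_variation=bool(group.attrs["per_frame_variation"]),
        frame_index=int(group.attrs["frame_index"]),
    )


def save_patterns(path: str | Path, patterns: list[SamplingPattern]) -> None:
    with h5py.File(path, "w") as fh:
        for i, pat in enumerate(patterns):
            _write_pattern(fh.create_group(f"pattern_{i:05d}"), pat)


def load_patterns(path: str | Path) -> list[SamplingPattern]:
    with h5py.File(path, "r") as fh:
        return [_read_pattern(fh[k]) for k in sorted(fh.keys())]


def save_kframes(path: str | Path, kframes: list[KSpaceFrame]) -> None:
    with h5py.File(path, "w") as fh:
        for i, kf in enumerate(kframes):
            g = fh.create_group(f"frame_{i:05d}")
            g.create_dataset("samples", data=kf.samples)
            g.attrs["noise_sigma"] = kf.noise_sigma
            _write_pattern(g.create_group("pattern"), kf.pattern)


def load_kframes(path: str | Path) -> list[KSpaceFrame]:
    out = []
    with h5py.File(path, "r") as fh:
        for k in sorted(fh.keys()):
            g = fh[k]
            out.append(
                KSpaceFrame(
                    samples=g["samples"][...],
                    pattern=_read_pattern(g["pattern"]),
                    noise_sigma=float(g.attrs["noise_sigma"]),
                )
            )
    return out


def save_dictionary(path: str | Path, dictionary: CardiacMotionDictionary) -> None:
    """Persist the dictionary in its lossless compact form.

    The pixel means and centered training matrix determine every ``C_l``
    exactly; storing the dense T x N^2 x N^2 stack would be prohibitively
    large at clinically relevant grid sizes.
    """
    with h5py.File(path, "w") as fh:
        fh.create_dataset("means", data=dictionary.means_)
        fh.create_dataset("centered", data=dictionary._Y)
        fh.attrs["T"] = dictionary.T_
        fh.attrs["N"] = dictionary.N_
        fh.attrs["pinv_tol"] = dictionary.pinv_tol


def load_dictionary(path: str | Path) -> CardiacMotionDictionary:
    with h5py.File(path, "r") as fh:
        means = fh["means"][...]
        Y = fh["centered"][...]
        T = int(fh.attrs["T"])
        N = int(fh.attrs["N"])
        tol = float(fh.attrs["pinv_tol"])
    frames = (Y + means[:, None]).T.reshape(T, N, N)
    return CardiacMotionDictionary(pinv_tol=tol).fit(frames)


def export_magnitude_nifti(path: str | Path, series: CineSeries) -> None:
    """Write |frames| as a 3-D NIfTI volume (x, y, time) for visual inspection."""
    import nibabel as nib

    mag = np.abs(series.frames).transpose(1, 2, 0).astype(np.float32)
    nib.save(nib.Nifti1Image(mag, affine=np.eye(4)), str(path))
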