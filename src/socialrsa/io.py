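"""On-disk layout for pattern datasets: NIfTI volumes plus a JSON sidecar.

A dataset directory contains ``mask.nii.gz``, one 4-D beta image per
subject and repeat (x, y, z, condition), and ``manifest.json`` recording
condition labels, subject/repeat file names, and grid metadata, which
suffices to reload the dataset exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .geometry import PatternDataset, VolumeGrid, load_mask_nifti, save_mask_nifti

__all__ = ["save_pattern_dataset", "load_pattern_dataset"]


def save_pattern_dataset(dataset: PatternDataset, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_mask_nifti(dataset.mask, outdir / "mask.nii.gz")
    affine = dataset.grid.default_affine()
    manifest = {
        "condition_labels": list(dataset.condition_labels),
        "voxel_size": list(dataset.grid.voxel_size),
        "shape": list(dataset.grid.shape),
        "subjects": {},
    }
    members = tuple(dataset.mask.members.T)
    for subj, repeats in dataset.subjects.items():
        files = []
        for r, pattern in enumerate(repeats):
            vol = np.zeros(dataset.grid.shape + (pattern.shape[0],),
                           dtype=np.float32)
            for c in range(pattern.shape[0]):
                vol[members + (c,)] = pattern[c]
            fname = f"{subj}_rep-{r + 1:02d}_beta.nii.gz"
            nib.save(nib.Nifti1Image(vol, affine), str(outdir / fname))
            files.append(fname)
        manifest["subjects"][subj] = files
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


def load_pattern_dataset(path) -> PatternDataset:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    grid = VolumeGrid(tuple(manifest["shape"]),
                      tuple(manifest["voxel_size"]))
    mask = load_mask_nifti(path / "mask.nii.gz", grid)
    members = tuple(mask.members.T)
    subjects: dict[str, list[np.ndarray]] = {}
    for subj, files in manifest["subjects"].items():
        repeats = []
        for fname in files:
            vol = np.asarray(nib.load(str(path / fname)).dataobj, dtype=float)
            pattern = np.stack(
                [vol[members + (c,)] for c in range(vol.shape[3])]
            )
            repeats.append(pattern)
        subjects[subj] = repeats
    return PatternDataset(subjects, tuple(manifest["condition_labels"]),
                          grid, mask)
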