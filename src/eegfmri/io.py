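"""File formats: NIfTI volumes/masks/atlas, delimited EEG matrices with JSON
sidecars (EDF read via MNE when available), metric-table TSVs, and run
configuration JSON.

Conventions: BOLD data are stored as float32 NIfTI with the repetition time
in ``pixdim[4]``; atlas labels as uint16; masks as uint8.  EEG matrices are
tab-separated ``sources x samples`` with a sidecar
``{"rate_hz": ..., "source_network_id": [...]}``.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .eeg_metrics import SourceSignalSet
from .fmri_metrics import VolumeSeries
from .synth import Cohort

__all__ = [
    "write_volume", "read_volume", "write_eeg", "read_eeg",
    "write_cohort", "read_cohort", "read_metric_table",
]

_MASK_NAMES = ("gray", "white", "csf", "vessel")


def write_volume(v: VolumeSeries, path: str | Path) -> None:
    """4-D BOLD as float32 NIfTI (TR in pixdim[4]) with ``*_mask_<name>`` and
    ``*_fbv`` companions beside it."""
    path = Path(path)
    img = nib.Nifti1Image(v.data.astype(np.float32), affine=np.eye(4))
    img.header["pixdim"][4] = v.tr_seconds
    nib.save(img, path)
    stem = path.name.replace(".nii.gz", "").replace(".nii", "")
    for name, m in v.masks.items():
        nib.save(nib.Nifti1Image(m.astype(np.uint8), np.eye(4)),
                 path.parent / f"{stem}_mask_{name}.nii.gz")
    if v.fbv is not None:
        nib.save(nib.Nifti1Image(v.fbv.astype(np.float32), np.eye(4)),
                 path.parent / f"{stem}_fbv.nii.gz")


def read_volume(path: str | Path, tr_seconds: float | None = None) -> VolumeSeries:
    """Load a 4-D NIfTI plus any mask/fBV companions written by
    :func:`write_volume`.

    TR is taken from the header's pixdim[4] unless overridden; a missing TR
    (0 in the header) without an override raises.  3-D files are rejected
    with a shape error; non-finite voxels are rejected with their location.
    """
    path = Path(path)
    img = nib.load(path)
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected a 4-D BOLD file, got {data.ndim}-D: {path}")
    if tr_seconds is None:
        tr_seconds = float(img.header["pixdim"][4])
        if tr_seconds <= 0:
            raise ValueError(f"no TR in the header of {path}; pass tr_seconds explicitly")
    stem = path.name.replace(".nii.gz", "").replace(".nii", "")
    masks = {}
    for name in _MASK_NAMES:
        mp = path.parent / f"{stem}_mask_{name}.nii.gz"
        if mp.exists():
            masks[name] = np.asanyarray(nib.load(mp).dataobj) > 0
    fbv = None
    fp = path.parent / f"{stem}_fbv.nii.gz"
    if fp.exists():
        fbv = np.asanyarray(nib.load(fp).dataobj, dtype=float)
    return VolumeSeries(data=data, tr_seconds=tr_seconds, masks=masks, fbv=fbv)


def write_atlas(atlas: np.ndarray, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(atlas.astype(np.uint16), np.eye(4)), Path(path))


def read_atlas(path: str | Path) -> np.ndarray:
    return np.asanyarray(nib.load(Path(path)).dataobj).astype(np.uint16)


def write_eeg(s: SourceSignalSet, path: str | Path) -> None:
    """Sources x samples TSV (%.10g) plus a JSON sidecar with the sampling
    rate and per-source network labels."""
    path = Path(path)
    np.savetxt(path, s.data, delimiter="\t", fmt="%.10g")
    sidecar = {"rate_hz": s.rate_hz,
               "source_network_id": [int(x) for x in s.source_network]}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_eeg(path: str | Path, sidecar: str | Path | None = None) -> SourceSignalSet:
    """Read a delimited source matrix (or an EDF file) with its JSON sidecar.

    For delimited input the sidecar must supply ``rate_hz`` (an informative
    error names the key) and may supply ``source_network_id``.  EDF input is
    read through MNE; the sidecar then maps channels to networks.
    """
    path = Path(path)
    sidecar = Path(sidecar) if sidecar else path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    if path.suffix.lower() == ".edf":
        import mne
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data, rate = raw.get_data(), raw.info["sfreq"]
    else:
        try:
            data = np.loadtxt(path, delimiter="\t", ndmin=2)
        except ValueError as err:
            raise ValueError(f"ragged or non-numeric row in {path}: {err}") from err
        if "rate_hz" not in meta:
            raise ValueError(f"sampling rate missing: add 'rate_hz' to {sidecar}")
        rate = float(meta["rate_hz"])
    networks = np.asarray(meta.get("source_network_id", np.zeros(data.shape[0])),
                          dtype=int)
    return SourceSignalSet(data=data, rate_hz=rate, source_network=networks)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Persist a synthetic cohort: per-participant BOLD + EEG, the shared
    atlas, and the ground truth as JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_atlas(cohort.atlas, out / "atlas.nii.gz")
    for p in cohort.participants:
        pdir = out / f"sub-{p.pid:02d}"
        pdir.mkdir(exist_ok=True)
        write_volume(p.volume, pdir / "bold.nii.gz")
        write_eeg(p.eeg, pdir / "eeg.tsv")
    t = cohort.truth
    truth = {"sex": t.sex.tolist(), "latent": t.latent.tolist(),
             "bold_gain": t.bold_gain.tolist(),
             "confound_gain": None if t.confound_gain is None else t.confound_gain.tolist(),
             "references": [r.tolist() for r in t.references],
             "config": {k: (v if not isinstance(v, np.generic) else v.item())
                        for k, v in vars(t.config).items()}}
    (out / "ground_truth.json").write_text(json.dumps(truth))


def read_cohort(in_dir: str | Path):
    """Load the per-participant volumes/EEG and atlas written by
    :func:`write_cohort` (ground truth is returned as a plain dict)."""
    from .synth import Participant

    root = Path(in_dir)
    atlas = read_atlas(root / "atlas.nii.gz")
    participants = []
    for pdir in sorted(root.glob("sub-*")):
        pid = int(pdir.name.split("-")[1])
        participants.append(Participant(
            pid=pid,
            volume=read_volume(pdir / "bold.nii.gz"),
            eeg=read_eeg(pdir / "eeg.tsv")))
    truth_path = root / "ground_truth.json"
    truth = json.loads(truth_path.read_text()) if truth_path.exists() else None
    return participants, atlas, truth


def read_metric_table(path: str | Path) -> pd.DataFrame:
    """Long-format metric TSV: participant, network, metric, state, value."""
    df = pd.read_csv(path, sep="\t")
    required = {"participant", "network", "metric", "state", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metric table {path} lacks columns: {sorted(missing)}")
    return df
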