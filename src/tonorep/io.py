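"""File formats: NIfTI-1 volumes and labels, JSON designs, WAV sounds, TSV tables.

Conventions: the NIfTI affine (RAS+) is authoritative for mm positions;
voxel indices are 0-based everywhere in code.  The repetition time of a 4D
series is stored both in pixdim[4] and in a JSON sidecar; on read the
sidecar wins.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.io import wavfile

from .designs import BlockDesign, FrequencyProgression
from .matching import N_SAMPLES, SAMPLE_RATE, MatchedSets, SoundStimulus
from .sheet import NAME_OF, GroundTruthMap
from .volume import VolumeSeries

__all__ = [
    "FormatError",
    "write_volume_series",
    "read_volume_series",
    "write_label_volume",
    "read_label_volume",
    "write_ground_truth",
    "write_design",
    "read_design",
    "write_progression",
    "read_progression",
    "write_wav",
    "read_wav",
    "write_matched_sets",
]


class FormatError(ValueError):
    """A file does not match the expected format."""


def _sidecar(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_volume_series(vs: VolumeSeries, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(vs.data.astype(np.float32), vs.affine)
    zooms = tuple(np.abs(np.diag(vs.affine)[:3])) + (vs.tr,)
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    sidecar = _sidecar(path)
    sidecar.write_text(json.dumps({"tr_s": vs.tr, "meta": _jsonable(vs.meta)}, indent=2))
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def read_volume_series(path: str | Path) -> VolumeSeries:
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
    except Exception as exc:                   # malformed file -> explicit error
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    if data.ndim != 4:
        raise FormatError(f"{path}: expected a 4D series, got {data.ndim}D")
    tr = None
    sidecar = _sidecar(path)
    meta: dict = {}
    if sidecar.exists():
        side = json.loads(sidecar.read_text())
        tr = side.get("tr_s")
        meta = side.get("meta", {})
    if tr is None:
        zooms = img.header.get_zooms()
        if len(zooms) >= 4 and zooms[3] > 0:
            tr = float(zooms[3])
    if tr is None or tr <= 0:
        raise FormatError(f"{path}: repetition time missing from header and sidecar")
    return VolumeSeries(data=data.astype(float), tr=float(tr), affine=img.affine, meta=meta)


def write_label_volume(
    labels: np.ndarray, affine: np.ndarray, path: str | Path, table: dict | None = None
) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(labels.astype(np.int16), affine)
    nib.save(img, str(path))
    if table is not None:
        _sidecar(path).write_text(json.dumps(_jsonable(table), indent=2))
    return path


def read_label_volume(path: str | Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    try:
        img = nib.load(str(path))
        labels = np.asarray(img.dataobj).astype(np.int16)
    except Exception as exc:
        raise FormatError(f"cannot read label volume {path}: {exc}") from exc
    sidecar = _sidecar(path)
    table = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return labels, table


def write_ground_truth(gt: GroundTruthMap, stem: str | Path) -> dict[str, Path]:
    """Label NIfTI + best-frequency NIfTI + JSON sidecar with the spec."""
    stem = Path(stem)
    affine = np.diag([gt.spec.voxel_size_mm] * 3 + [1.0])
    paths = {}
    paths["labels"] = write_label_volume(gt.labels, affine, stem.with_suffix(".labels.nii.gz"))
    bf_img = nib.Nifti1Image(np.nan_to_num(gt.best_frequency, nan=0.0).astype(np.float32), affine)
    paths["best_frequency"] = stem.with_suffix(".bf.nii.gz")
    nib.save(bf_img, str(paths["best_frequency"]))
    side = {
        "seed": gt.seed,
        "hemisphere": gt.spec.hemisphere,
        "label_names": {str(k): v for k, v in NAME_OF.items()},
        "spec": _jsonable(vars(gt.spec) | {"frequencies": list(gt.spec.frequencies)}),
    }
    paths["sidecar"] = stem.with_suffix(".json")
    paths["sidecar"].write_text(json.dumps(side, indent=2))
    return paths


def write_design(design: BlockDesign, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(design.to_dict(), indent=2))
    return path


def read_design(path: str | Path) -> BlockDesign:
    return BlockDesign.from_dict(json.loads(Path(path).read_text()))


def write_progression(prog: FrequencyProgression, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(prog.to_dict(), indent=2))
    return path


def read_progression(path: str | Path) -> FrequencyProgression:
    return FrequencyProgression.from_dict(json.loads(Path(path).read_text()))


def write_wav(sound: SoundStimulus, path: str | Path) -> Path:
    path = Path(path)
    pcm = np.clip(sound.waveform, -1.0, 1.0)
    wavfile.write(str(path), SAMPLE_RATE, (pcm * 32767).astype(np.int16))
    return path


def read_wav(path: str | Path, identifier: str | None = None) -> SoundStimulus:
    path = Path(path)
    try:
        rate, data = wavfile.read(str(path))
    except Exception as exc:
        raise FormatError(f"cannot read WAV file {path}: {exc}") from exc
    if rate != SAMPLE_RATE:
        raise FormatError(f"{path}: expected {SAMPLE_RATE} Hz, got {rate}")
    if data.ndim == 2:                         # stereo duplicated from mono
        data = data.mean(axis=1)
    if data.size != N_SAMPLES:
        raise FormatError(f"{path}: expected {N_SAMPLES} samples, got {data.size}")
    wave = data.astype(float) / 32767.0
    return SoundStimulus(waveform=wave, identifier=identifier or path.stem)


def write_matched_sets(ms: MatchedSets, stem: str | Path) -> dict[str, Path]:
    """MatchedSets summary as JSON plus per-point p-values as TSV."""
    stem = Path(stem)
    paths = {"summary": stem.with_suffix(".json")}
    paths["summary"].write_text(json.dumps(ms.to_dict(), indent=2))
    if ms.result is not None:
        pvals = pd.concat(
            [
                pd.DataFrame(
                    {"family": "envelope", "index": np.arange(ms.result.envelope_p.size),
                     "p": ms.result.envelope_p}
                ),
                pd.DataFrame(
                    {"family": "spectrum", "index": np.arange(ms.result.spectrum_p.size),
                     "p": ms.result.spectrum_p}
                ),
            ],
            ignore_index=True,
        )
        paths["pvalues"] = stem.with_suffix(".pvalues.tsv")
        pvals.to_csv(paths["pvalues"], sep="\t", index=False, float_format="%.4g")
    return paths


def write_tonotopic_map(tmap, stem: str | Path, voxel_size_mm: float = 1.5) -> dict[str, Path]:
    """Best-frequency, r and mask NIfTIs plus a JSON sidecar and TSV summary."""
    from .tonotopy import TonotopicMap  # local import to avoid a cycle

    assert isinstance(tmap, TonotopicMap)
    stem = Path(stem)
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    paths: dict[str, Path] = {}
    for field_name, arr, dtype in (
        ("bf", np.nan_to_num(tmap.best_frequency, nan=0.0), np.float32),
        ("r", np.nan_to_num(tmap.r, nan=0.0), np.float32),
        ("mask", tmap.mask.astype(np.int16), np.int16),
    ):
        p = stem.with_suffix(f".{field_name}.nii.gz")
        nib.save(nib.Nifti1Image(arr.astype(dtype), affine), str(p))
        paths[field_name] = p
    side = {
        "frequencies_hz": list(tmap.frequencies),
        "tr_s": tmap.tr,
        "step_duration_s": tmap.step_duration,
    }
    paths["sidecar"] = stem.with_suffix(".map.json")
    paths["sidecar"].write_text(json.dumps(side, indent=2))
    valid = tmap.mask & np.isfinite(tmap.best_frequency)
    summary = pd.DataFrame(
        {
            "frequency_hz": tmap.frequencies,
            "n_voxels": [
                int((valid & np.isclose(tmap.best_frequency, f)).sum())
                for f in tmap.frequencies
            ],
        }
    )
    paths["summary"] = stem.with_suffix(".summary.tsv")
    summary.to_csv(paths["summary"], sep="\t", index=False)
    return paths


def read_tonotopic_map(stem: str | Path):
    """Rebuild a TonotopicMap written by :func:`write_tonotopic_map`."""
    from .tonotopy import TonotopicMap

    stem = Path(stem)
    side = json.loads(stem.with_suffix(".map.json").read_text())
    bf = np.asarray(nib.load(str(stem.with_suffix(".bf.nii.gz"))).dataobj).astype(float)
    r = np.asarray(nib.load(str(stem.with_suffix(".r.nii.gz"))).dataobj).astype(float)
    mask = np.asarray(nib.load(str(stem.with_suffix(".mask.nii.gz"))).dataobj).astype(bool)
    bf[bf == 0] = np.nan
    freqs = tuple(side["frequencies_hz"])
    asc = np.array(sorted(freqs))
    with np.errstate(invalid="ignore"):
        idx = np.argmin(np.abs(np.log2(bf[..., None]) - np.log2(asc)[None, None, None, :]), axis=-1).astype(float)
    idx[~np.isfinite(bf)] = np.nan
    return TonotopicMap(
        best_frequency=bf,
        r=r,
        time_to_peak=np.full_like(r, np.nan),
        ascending_index=idx,
        mask=mask,
        frequencies=freqs,
        tr=side["tr_s"],
        step_duration=side["step_duration_s"],
    )
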