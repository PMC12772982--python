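"""File formats: ENVI cubes, portable arrays, PNG masks, landmark CSVs,
homography JSON and scene manifests."""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .consensus import AnnotationSet
from .registration import Homography, LandmarkSet
from .spectral import Hypercube, WavelengthGrid

__all__ = [
    "write_envi",
    "read_envi",
    "write_portable_cube",
    "read_portable_cube",
    "read_cube",
    "write_mask_png",
    "read_mask_png",
    "write_landmarks_csv",
    "read_landmarks_csv",
    "write_homography_json",
    "read_homography_json",
    "write_annotation_manifest",
    "read_annotation_manifest",
    "write_rgb_png",
    "write_consensus_png",
    "write_subject_scene",
    "write_cohort_scenes",
]

_ENVI_DTYPES = {4: np.float32, 5: np.float64}
_ENVI_CODES = {np.dtype(np.float32): 4, np.dtype(np.float64): 5}


def write_envi(cube: Hypercube, base_path: str | Path, interleave: str = "bsq") -> Path:
    """Write ``<base>.hdr`` + ``<base>.raw`` (float32, little-endian)."""
    interleave = interleave.lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise ValueError(f"unknown interleave {interleave!r}")
    base = Path(base_path)
    h, w, b = cube.shape
    data = cube.reflectance.astype("<f4")
    if interleave == "bsq":
        ordered = np.transpose(data, (2, 0, 1))  # band, line, sample
    elif interleave == "bil":
        ordered = np.transpose(data, (0, 2, 1))  # line, band, sample
    else:
        ordered = data  # line, sample, band
    raw_path = base.with_suffix(".raw")
    ordered.tofile(raw_path)
    wl = ", ".join(f"{v:g}" for v in cube.grid.centers)
    lines = [
        "ENVI",
        "file type = ENVI Standard",
        f"samples = {w}",
        f"lines = {h}",
        f"bands = {b}",
        "header offset = 0",
        "data type = 4",
        f"interleave = {interleave}",
        "byte order = 0",
        "wavelength units = nm",
        f"wavelength = {{ {wl} }}",
    ]
    if cube.pixel_pitch_mm is not None:
        lines.append(f"pixel size = {{ {cube.pixel_pitch_mm:g}, {cube.pixel_pitch_mm:g} }}")
    base.with_suffix(".hdr").write_text("\n".join(lines) + "\n")
    return base.with_suffix(".hdr")


def _parse_envi_header(text: str) -> dict[str, str]:
    # collapse brace-delimited multi-line values, then split on first '='
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields: dict[str, str] = {}
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def read_envi(hdr_path: str | Path) -> Hypercube:
    """Read an ENVI cube (``.hdr`` text header + raw binary, BSQ/BIL/BIP)."""
    hdr_path = Path(hdr_path)
    fields = _parse_envi_header(hdr_path.read_text())
    w = int(fields["samples"])
    h = int(fields["lines"])
    b = int(fields["bands"])
    dtype_code = int(fields.get("data type", "4"))
    if dtype_code not in _ENVI_DTYPES:
        raise ValueError(f"unsupported ENVI data type {dtype_code}")
    dtype = np.dtype(_ENVI_DTYPES[dtype_code])
    if int(fields.get("byte order", "0")) == 1:
        dtype = dtype.newbyteorder(">")
    interleave = fields.get("interleave", "bsq").lower()
    offset = int(fields.get("header offset", "0"))

    wl_match = re.search(r"\{([^}]*)\}", fields.get("wavelength", ""))
    if not wl_match:
        raise ValueError("ENVI header has no wavelength list")
    centers = np.array([float(v) for v in wl_match.group(1).split(",") if v.strip()])
    if centers.size != b:
        raise ValueError("wavelength list length does not match band count")
    steps = np.diff(centers)
    if centers.size > 1 and not np.allclose(steps, steps[0], atol=1e-6):
        raise ValueError("only uniform wavelength grids are supported")
    step = float(steps[0]) if centers.size > 1 else 1.0
    grid = WavelengthGrid(start_nm=float(centers[0]), step_nm=step, n_bands=b)

    raw_path = hdr_path.with_suffix(".raw")
    if not raw_path.exists():
        raw_path = hdr_path.with_suffix(".img")
    data = np.fromfile(raw_path, dtype=dtype, offset=offset, count=h * w * b)
    if interleave == "bsq":
        cube = np.transpose(data.reshape(b, h, w), (1, 2, 0))
    elif interleave == "bil":
        cube = np.transpose(data.reshape(h, b, w), (0, 2, 1))
    elif interleave == "bip":
        cube = data.reshape(h, w, b)
    else:
        raise ValueError(f"unknown interleave {interleave!r}")

    pitch = None
    pix_match = re.search(r"\{([^}]*)\}", fields.get("pixel size", ""))
    if pix_match:
        pitch = float(pix_match.group(1).split(",")[0])
    return Hypercube(cube.astype(np.float64), grid, pixel_pitch_mm=pitch)


def write_portable_cube(cube: Hypercube, base_path: str | Path) -> Path:
    """Write ``<base>.npy`` plus a JSON sidecar with the wavelength grid."""
    base = Path(base_path)
    np.save(base.with_suffix(".npy"), cube.reflectance)
    sidecar = {
        "start_nm": cube.grid.start_nm,
        "step_nm": cube.grid.step_nm,
        "n_bands": cube.grid.n_bands,
        "pixel_pitch_mm": cube.pixel_pitch_mm,
    }
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return base.with_suffix(".npy")


def read_portable_cube(base_path: str | Path) -> Hypercube:
    base = Path(base_path)
    meta = json.loads(base.with_suffix(".json").read_text())
    grid = WavelengthGrid(meta["start_nm"], meta["step_nm"], meta["n_bands"])
    data = np.load(base.with_suffix(".npy"))
    return Hypercube(data, grid, pixel_pitch_mm=meta.get("pixel_pitch_mm"))


def read_cube(path: str | Path) -> Hypercube:
    """Dispatch on extension: ``.hdr`` -> ENVI, ``.npy``/bare -> portable."""
    path = Path(path)
    if path.suffix == ".hdr":
        return read_envi(path)
    return read_portable_cube(path.with_suffix("") if path.suffix else path)


def write_mask_png(mask: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    img = Image.fromarray((np.asarray(mask, dtype=bool) * 255).astype(np.uint8), mode="L")
    img.save(path)
    return path


def read_mask_png(path: str | Path) -> np.ndarray:
    arr = np.asarray(Image.open(path).convert("L"))
    return arr >= 128


def write_landmarks_csv(landmarks: LandmarkSet, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "src_x": landmarks.src[:, 0],
            "src_y": landmarks.src[:, 1],
            "dst_x": landmarks.dst[:, 0],
            "dst_y": landmarks.dst[:, 1],
        }
    )
    df.to_csv(path, index=False)
    return path


def read_landmarks_csv(
    path: str | Path, source_frame: str = "colposcope", destination_frame: str = "hsi"
) -> LandmarkSet:
    df = pd.read_csv(path)
    return LandmarkSet(
        src=df[["src_x", "src_y"]].to_numpy(dtype=np.float64),
        dst=df[["dst_x", "dst_y"]].to_numpy(dtype=np.float64),
        source_frame=source_frame,
        destination_frame=destination_frame,
    )


def write_homography_json(H: Homography, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "h": [float(v) for v in H.h.ravel()],
        "layout": "row-major",
        "normalization": "h33" if abs(H.h[2, 2] - 1.0) < 1e-12 else "frobenius",
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path


def read_homography_json(path: str | Path) -> Homography:
    payload = json.loads(Path(path).read_text())
    return Homography(np.array(payload["h"], dtype=np.float64).reshape(3, 3))


def write_annotation_manifest(
    sets: Sequence[AnnotationSet], directory: str | Path, subject_id: str
) -> Path:
    """Write each mask as 8-bit PNG plus a JSON manifest tying them together."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for s in sets:
        masks = {}
        for cls, mask in sorted(s.masks.items()):
            name = f"{subject_id}_{s.examiner_id}_{cls}.png"
            write_mask_png(mask, directory / name)
            masks[cls] = name
        entries.append({"examiner_id": s.examiner_id, "frame": s.frame, "masks": masks})
    manifest = {"subject_id": subject_id, "annotations": entries}
    path = directory / f"{subject_id}_annotations.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def write_rgb_png(rgb: np.ndarray, path: str | Path) -> Path:
    """Write a float [0, 1] (H, W, 3) image as 8-bit RGB PNG."""
    path = Path(path)
    arr = np.clip(np.asarray(rgb, dtype=np.float64), 0.0, 1.0)
    Image.fromarray((arr * 255).round().astype(np.uint8), mode="RGB").save(path)
    return path


def write_consensus_png(values: np.ndarray, n_examiners: int, path: str | Path) -> Path:
    """Store a consensus map as 16-bit PNG of raw counts (value * n) + JSON meta."""
    path = Path(path)
    counts = np.rint(np.asarray(values) * n_examiners).astype(np.uint16)
    Image.fromarray(counts).save(path)
    path.with_suffix(".json").write_text(
        json.dumps({"n_examiners": n_examiners, "encoding": "count"}, sort_keys=True)
    )
    return path


def write_subject_scene(scene, directory: str | Path) -> dict:
    """Persist one synthetic subject scene; returns its manifest entry.

    Written per subject: ENVI cube, examiner annotation manifest (colposcope
    frame), ground-truth annotation manifest (HSI frame), landmark CSV, the
    true homography and the pseudo-colposcope RGB view.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sid = scene.subject_id
    write_envi(scene.cube, directory / f"{sid}_cube")
    ann_path = write_annotation_manifest(scene.examiner_annotations, directory, sid)
    truth_dir = directory / "truth"
    truth_path = write_annotation_manifest([scene.truth], truth_dir, sid)
    lm_path = write_landmarks_csv(scene.landmarks, directory / f"{sid}_landmarks.csv")
    write_homography_json(scene.H_true, directory / f"{sid}_H_true.json")
    write_rgb_png(scene.colposcope_rgb, directory / f"{sid}_colposcope.png")
    return {
        "subject_id": sid,
        "cube": f"{sid}_cube.hdr",
        "annotations": str(ann_path.relative_to(directory)),
        "truth": str(truth_path.relative_to(directory)),
        "landmarks": str(lm_path.relative_to(directory)),
    }


def write_cohort_scenes(scenes: Sequence, directory: str | Path) -> Path:
    """Write all scenes plus a cohort manifest consumable by the pipeline."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = [write_subject_scene(s, directory) for s in scenes]
    path = directory / "cohort_manifest.json"
    path.write_text(json.dumps({"subjects": entries}, indent=2, sort_keys=True))
    return path


def read_annotation_manifest(path: str | Path) -> list[AnnotationSet]:
    path = Path(path)
    manifest = json.loads(path.read_text())
    out = []
    for entry in manifest["annotations"]:
        masks = {
            cls: read_mask_png(path.parent / fname)
            for cls, fname in entry["masks"].items()
        }
        out.append(
            AnnotationSet(
                subject_id=manifest["subject_id"],
                examiner_id=entry["examiner_id"],
                masks=masks,
                frame=entry.get("frame", "colposcope"),
            )
        )
    return out
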