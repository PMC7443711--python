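"""HDF5 persistence for phantoms and simulated image sets.

One file per phantom:

    /model/label, /model/body_id, /model/so2_true     voxel volumes
    /model/mu_a/<lambda>, /model/mu_s/<lambda>        mm^-1, per wavelength
    /model/g, /model/n
    /p0/<lambda>                                      initial pressure
    /recon/<lambda>                                   reconstructed image
    attrs: seeds, layer-sample parameters, grid spec, JSON metadata
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from paovox.acoustics import MultiwavelengthImage
from paovox.optics import LayerSample
from paovox.phantom import GridSpec, TissueModel

__all__ = ["save_phantom_record", "load_model", "load_image_set", "load_p0"]


def _lam_key(lam: float) -> str:
    return f"{float(lam):g}"


def save_phantom_record(
    path: str | Path,
    model: TissueModel,
    image: MultiwavelengthImage | None = None,
    p0_by_lambda: dict[float, np.ndarray] | None = None,
    meta: dict | None = None,
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        g = f.create_group("model")
        g.create_dataset("label", data=model.label, compression="gzip")
        g.create_dataset("body_id", data=model.body_id, compression="gzip")
        g.create_dataset("so2_true", data=model.so2_true, compression="gzip")
        g.create_dataset("g", data=model.g, compression="gzip")
        g.create_dataset("n", data=model.n, compression="gzip")
        mu_a = g.create_group("mu_a")
        mu_s = g.create_group("mu_s")
        for lam in model.wavelengths:
            mu_a.create_dataset(
                _lam_key(lam), data=model.mu_a[lam], compression="gzip"
            )
            mu_s.create_dataset(
                _lam_key(lam), data=model.mu_s[lam], compression="gzip"
            )
        g.attrs["gamma"] = model.gamma
        g.attrs["grid"] = json.dumps(
            {
                "nz": model.grid.nz,
                "ny": model.grid.ny,
                "nx": model.grid.nx,
                "dx_mm": model.grid.dx_mm,
            }
        )
        if model.layer_sample is not None:
            g.attrs["layer_sample"] = json.dumps(vars(model.layer_sample))
        g.attrs["meta"] = json.dumps(model.meta)
        if p0_by_lambda is not None:
            grp = f.create_group("p0")
            for lam, vol in p0_by_lambda.items():
                grp.create_dataset(_lam_key(lam), data=vol, compression="gzip")
        if image is not None:
            grp = f.create_group("recon")
            for i, lam in enumerate(image.wavelengths):
                grp.create_dataset(
                    _lam_key(lam), data=image.data[i], compression="gzip"
                )
            grp.attrs["meta"] = json.dumps(image.meta)
        f.attrs["meta"] = json.dumps(meta or {})


def load_model(path: str | Path) -> TissueModel:
    with h5py.File(path, "r") as f:
        g = f["model"]
        grid_d = json.loads(g.attrs["grid"])
        grid = GridSpec(**grid_d)
        sample = None
        if "layer_sample" in g.attrs:
            sample = LayerSample(**json.loads(g.attrs["layer_sample"]))
        mu_a = {float(k): np.array(v) for k, v in g["mu_a"].items()}
        mu_s = {float(k): np.array(v) for k, v in g["mu_s"].items()}
        return TissueModel(
            grid=grid,
            label=np.array(g["label"]),
            body_id=np.array(g["body_id"]),
            so2_true=np.array(g["so2_true"]),
            mu_a=mu_a,
            mu_s=mu_s,
            g=np.array(g["g"]),
            n=np.array(g["n"]),
            gamma=float(g.attrs["gamma"]),
            layer_sample=sample,
            meta=json.loads(g.attrs["meta"]),
        )


def load_image_set(path: str | Path) -> MultiwavelengthImage:
    with h5py.File(path, "r") as f:
        grp = f["recon"]
        lams = sorted(float(k) for k in grp.keys())
        data = np.stack([np.array(grp[_lam_key(l)]) for l in lams])
        meta = json.loads(grp.attrs.get("meta", "{}"))
        return MultiwavelengthImage(
            data=data, wavelengths=tuple(lams), meta=meta
        )


def load_p0(path: str | Path) -> dict[float, np.ndarray]:
    with h5py.File(path, "r") as f:
        grp = f["p0"]
        return {float(k): np.array(v) for k, v in grp.items()}
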