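"""HDF5 containers for datasets and trained-model parameters."""

from __future__ import annotations

import json

import h5py

from .simulate import GroundTruth

__all__ = ["save_dataset", "load_dataset", "save_model", "load_model_arrays"]


def save_dataset(path, truth: GroundTruth, attrs: dict | None = None):
    """Write a simulated dataset: /data, /state_course or /alpha, /covariances, /means."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=truth.data)
        fh.create_dataset("covariances", data=truth.covariances)
        fh.create_dataset("means", data=truth.means)
        if truth.state_course is not None:
            fh.create_dataset("state_course", data=truth.state_course)
        if truth.alpha is not None:
            fh.create_dataset("alpha", data=truth.alpha)
        if truth.logits is not None:
            fh.create_dataset("logits", data=truth.logits)
        for key, val in (attrs or {}).items():
            fh.attrs[key] = val


def load_dataset(path) -> GroundTruth:
    with h5py.File(path, "r") as fh:
        return GroundTruth(
            data=fh["data"][()],
            covariances=fh["covariances"][()],
            means=fh["means"][()],
            state_course=fh["state_course"][()] if "state_course" in fh else None,
            alpha=fh["alpha"][()] if "alpha" in fh else None,
            logits=fh["logits"][()] if "logits" in fh else None,
        )


def save_model(path, trained):
    """Serialise trained parameters: /means, /cholesky, /temperature, /rnn/*."""
    mm = trained.mode_model
    with h5py.File(path, "w") as fh:
        fh.create_dataset("means", data=mm.means.value)
        fh.create_dataset("cholesky", data=mm.cholesky_flat.value)
        fh.create_dataset("temperature", data=mm.temperature)
        rnn = fh.create_group("rnn")
        rnn.create_dataset("model_W", data=mm.model_rnn.W.value)
        rnn.create_dataset("model_b", data=mm.model_rnn.b.value)
        rnn.create_dataset("g_mu_W", data=mm.g_mu.W.value)
        rnn.create_dataset("g_mu_b", data=mm.g_mu.b.value)
        rnn.create_dataset("g_sigma_W", data=mm.g_sigma.W.value)
        rnn.create_dataset("g_sigma_b", data=mm.g_sigma.b.value)
        inf = trained.inference_rnn
        rnn.create_dataset("inf_fwd_W", data=inf.blstm.fwd.W.value)
        rnn.create_dataset("inf_fwd_b", data=inf.blstm.fwd.b.value)
        rnn.create_dataset("inf_bwd_W", data=inf.blstm.bwd.W.value)
        rnn.create_dataset("inf_bwd_b", data=inf.blstm.bwd.b.value)
        rnn.create_dataset("f_m_W", data=inf.f_m.W.value)
        rnn.create_dataset("f_m_b", data=inf.f_m.b.value)
        rnn.create_dataset("f_s_W", data=inf.f_s.W.value)
        rnn.create_dataset("f_s_b", data=inf.f_s.b.value)
        fh.attrs["config"] = json.dumps(
            {k: v for k, v in vars(trained.config).items()}, default=str
        )


def load_model_arrays(path) -> dict:
    """Read back the raw parameter arrays of a saved model."""
    out = {}
    with h5py.File(path, "r") as fh:
        def visit(name, obj):
            if isinstance(obj, h5py.Dataset):
                out[name] = obj[()]
        fh.visititems(visit)
        out["config"] = json.loads(fh.attrs["config"]) if "config" in fh.attrs else {}
    return out
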