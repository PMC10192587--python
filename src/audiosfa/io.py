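"""Plain-format serialization: WAV audio, CSV tables, JSON feature spaces."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .cochlea import Cochleagram
from .sfa import FeatureSpace
from .stimuli import AudioStimulus

__all__ = ["write_wav", "read_wav", "write_metadata_csv",
           "write_cochleagram_csv", "read_cochleagram_csv",
           "write_feature_space", "read_feature_space",
           "write_marginal_csv"]


def write_wav(path, stim: AudioStimulus) -> None:
    wavfile.write(str(path), int(stim.rate), stim.samples.astype(np.float32))


def read_wav(path, label: str = "fixture") -> AudioStimulus:
    rate, data = wavfile.read(str(path))
    if data.ndim > 1:
        raise ValueError("only mono WAV files are supported")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / np.iinfo(data.dtype).max
    return AudioStimulus(np.asarray(data, dtype=np.float64), float(rate), label)


def write_metadata_csv(path, stimuli: list[AudioStimulus]) -> None:
    rows = [{"exemplar_id": s.exemplar_id, "label": s.label, "seed": s.seed,
             "duration": s.duration, "rate": s.rate} for s in stimuli]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_cochleagram_csv(path, C: Cochleagram) -> None:
    cols = [f"ch{(i):02d}_{f:.1f}Hz" for i, f in enumerate(C.center_freqs)]
    df = pd.DataFrame(C.values, columns=cols)
    df.attrs["rate"] = C.rate
    with open(path, "w") as fh:
        fh.write(f"# rate={C.rate}\n")
        df.to_csv(fh, index=False)


def read_cochleagram_csv(path) -> Cochleagram:
    with open(path) as fh:
        header = fh.readline()
        rate = float(header.strip().split("=")[1])
        df = pd.read_csv(fh)
    freqs = np.array([float(c.split("_")[1][:-2]) for c in df.columns])
    return Cochleagram(df.to_numpy(dtype=np.float64), rate, freqs)


def write_feature_space(path, space: FeatureSpace) -> None:
    payload = {
        "algorithm": space.algorithm,
        "weights": space.weights.tolist(),
        "offset": space.offset.tolist(),
        "spectrum": None if space.spectrum is None else space.spectrum.tolist(),
        "input_dim": space.input_dim,
        "expansion": space.expansion,
        "n_kept": space.n_kept,
        "rate": space.rate,
        "meta": {k: (int(v) if isinstance(v, (int, np.integer)) else v)
                 for k, v in space.meta.items()},
    }
    Path(path).write_text(json.dumps(payload))


def read_feature_space(path) -> FeatureSpace:
    d = json.loads(Path(path).read_text())
    return FeatureSpace(
        algorithm=d["algorithm"], weights=np.array(d["weights"]),
        offset=np.array(d["offset"]),
        spectrum=None if d["spectrum"] is None else np.array(d["spectrum"]),
        input_dim=d["input_dim"], expansion=d["expansion"],
        n_kept=d["n_kept"], rate=d["rate"], meta=d.get("meta", {}))


def write_marginal_csv(path, ms) -> None:
    pd.DataFrame({"temporal_modulation_hz": ms.marginal_axis,
                  "power": ms.marginal}).to_csv(path, index=False)
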