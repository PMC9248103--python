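"""WAV and table I/O.

Recordings are RIFF WAV, PCM mono (8/16/24/32-bit accepted on read;
written as 16-bit).  Stereo files are rejected with a clear error.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .acoustics import VoiceRecording

__all__ = ["read_wav", "write_wav", "write_manifest"]

_BIT_DEPTH = {np.dtype("uint8"): 8, np.dtype("int16"): 16, np.dtype("int32"): 32}


def read_wav(path) -> VoiceRecording:
    """Read a mono PCM WAV file into a :class:`VoiceRecording`.

    Samples are rescaled to float on a nominal ±1 full scale.
    """
    path = Path(path)
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(f"{path.name}: stereo/multichannel WAV not supported (got {data.shape[1]} channels)")
    if data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype == np.int16:
        samples = data.astype(np.float64) / 32768.0
    elif data.dtype == np.int32:  # 24-bit PCM is delivered as int32
        samples = data.astype(np.float64) / 2147483648.0
    elif np.issubdtype(data.dtype, np.floating):
        samples = data.astype(np.float64)
    else:
        raise ValueError(f"{path.name}: unsupported sample format {data.dtype}")
    return VoiceRecording(samples, rate, _BIT_DEPTH.get(data.dtype, 32), id=path.stem)


def write_wav(path, recording: VoiceRecording) -> None:
    """Write a recording as 16-bit PCM mono WAV."""
    x = np.clip(recording.samples, -1.0, 1.0)
    wavfile.write(Path(path), int(recording.sample_rate_hz), (x * 32767).astype(np.int16))


def write_manifest(path, entries: dict) -> None:
    Path(path).write_text(json.dumps(entries, indent=2, sort_keys=True, default=str))
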