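"""Standard 62-channel scalp montage (10-10 electrode placement system)."""

from __future__ import annotations

#: Ordered channel names of the 62-electrode 10-10 montage used by default.
MONTAGE_62: tuple[str, ...] = (
    "Fp1", "Fz", "F3", "F7", "FT9", "FC5", "FC1", "C3", "TP9", "CP5",
    "CP1", "Pz", "P3", "P7", "O1", "Oz", "P8", "TP10", "CP6", "CP2",
    "C4", "T8", "FT10", "FC6", "FC2", "F4", "F8", "Fp2", "AF7", "AF3",
    "AFz", "F1", "F5", "FT7", "FC3", "FCz", "C1", "C5", "TP7", "CP3",
    "P1", "P5", "PO7", "PO3", "POz", "PO4", "PO8", "P6", "P2", "CPz",
    "CP4", "TP8", "FC4", "FT8", "F6", "F2", "AF4", "AF8", "O2", "P4",
    "C6", "C2",
)


def channel_index(montage: tuple[str, ...] | list[str], name: str) -> int:
    """Return the position of *name* in *montage*, raising a clear error if absent."""
    try:
        return list(montage).index(name)
    except ValueError:
        raise KeyError(f"channel {name!r} is not in the montage") from None
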