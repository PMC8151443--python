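"""Shared constants for the sleep-staging pipeline.

Stages follow the AASM 5-class convention; the fixed order below is used
everywhere a stage axis appears (class weights, confusion matrices,
softmax outputs), so ties in an argmax resolve toward the earlier stage.
"""

STAGES: tuple[str, ...] = ("W", "N1", "N2", "N3", "REM")
STAGE_INDEX: dict[str, int] = {s: i for i, s in enumerate(STAGES)}

#: Length of one scoring epoch in seconds (AASM).
EPOCH_SEC: int = 30

#: Analysis sample rate after preprocessing (samples/s).
TARGET_RATE: int = 25

#: Samples per 30-s epoch at the analysis rate.
EPOCH_SAMPLES: int = EPOCH_SEC * TARGET_RATE

#: Preprocessing passband (Hz).
BAND_LOW: float = 0.5
BAND_HIGH: float = 12.0
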