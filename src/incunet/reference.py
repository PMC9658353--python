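"""Published whole-tumor evaluation of the five architectures on BraTS 2019
(dice, sensitivity, specificity), used as input to the comparison tables."""

PUBLISHED_METRICS: dict[str, tuple[float, float, float]] = {
    "baseline_unet": (0.7230, 0.6970, 0.8720),
    "mi_unet": (0.7980, 0.9361, 0.9429),
    "ds_mi_unet": (0.8313, 0.7267, 0.9992),
    "hybrid": (0.8201, 0.7326, 0.9980),
    "ds_hybrid": (0.8775, 0.9026, 0.9942),
}
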