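"""Shared helpers for the test suite."""

from cecmarkers.normalize import fold_change, round_half_up


def stable_screen_on_means(rpms: dict) -> bool:
    """The stable-CEC screen evaluated on noise-free per-class mean RPMs."""
    y, o, c, s = (rpms[k] for k in ("cec_young", "cec_old", "cec_culture",
                                    "stroma"))
    if not (y > 10 and o > 10 and c > 10):
        return False
    contrast = fold_change(y, s)
    if contrast.defined and round_half_up(contrast.value, 1) < 2:
        return False
    age = fold_change(y, o)
    return age.defined and 0.5 <= round_half_up(age.value, 1) <= 2.0
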