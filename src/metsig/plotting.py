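"""Optional Kaplan-Meier plotting for signature evaluations."""
from __future__ import annotations

import numpy as np


def plot_km_pair(km_high, km_low, ax=None, title: str | None = None):
    """Step-plot a high/low risk KM curve pair (high dashed red, low green)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for km, label, style in (
        (km_high, f"high risk (n={km.n})", dict(color="red", linestyle="--")),
        (km_low, f"low risk (n={km.n})", dict(color="green")),
    ):
        t = np.concatenate([[0.0], km.times])
        s = np.concatenate([[1.0], km.survival])
        ax.step(t, s, where="post", label=label, **style)
    ax.set_xlabel("time (months)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    return ax
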