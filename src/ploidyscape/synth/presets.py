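"""Packaged cohort presets.

Each preset YAML encodes the generative composition of a simulated mouse
cohort: the between-mouse distribution of the >=8n mononuclear fraction and
the binucleated fraction (for imaging presets), or a signature-exposure
vector (for catalog presets). Per-mouse >=8n probabilities are placed at
stratified normal quantiles of the preset distribution — a
variance-controlled cohort design whose sample mean equals the preset mean
by construction, so recovery experiments measure pipeline bias rather than
small-cohort sampling noise — while all remaining per-mouse parameters are
drawn stochastically from the seed.
"""

from __future__ import annotations

import importlib.resources

import numpy as np
import yaml
from scipy.stats import norm

from .scenes import SceneConfig

IMAGING_PRESETS = ("wt_2mo", "mcl1_2mo")
CATALOG_PRESETS = ("mcl1_tumour_ID",)


def load_preset(name: str) -> dict:
    """Load a packaged preset YAML by name (or a path to a YAML file)."""
    base = importlib.resources.files("ploidyscape") / "data" / "presets"
    candidate = base / f"{name}.yaml"
    try:
        text = candidate.read_text()
    except FileNotFoundError:
        with open(name) as fh:
            return yaml.safe_load(fh)
    return yaml.safe_load(text)


def sample_cohort(preset: str | dict, seed: int,
                  n_mice: int | None = None) -> list[SceneConfig]:
    """Build per-mouse SceneConfigs from an imaging preset.

    The >=8n mononuclear probability of mouse i is the (i+0.5)/m quantile of
    the preset's normal between-mouse distribution (shuffled across mice);
    4n and binucleated fractions are drawn from their preset distributions.
    """
    if isinstance(preset, str):
        preset = load_preset(preset)
    m = n_mice if n_mice is not None else int(preset.get("n_mice", 6))
    rng = np.random.default_rng(seed)

    p8_spec = preset["mononuclear_class_probs"]["p8_plus"]
    quantiles = (np.arange(m) + 0.5) / m
    p8 = norm.ppf(quantiles, loc=p8_spec["mean"], scale=p8_spec["sd"])
    p8 = np.clip(p8, 0.005, 0.6)
    rng.shuffle(p8)

    p4_spec = preset["mononuclear_class_probs"]["p4"]
    p4 = np.clip(rng.normal(p4_spec["mean"], p4_spec["sd"], size=m), 0.02, 0.6)
    f16 = float(preset["mononuclear_class_probs"].get("p16_given_8plus", 0.2))

    bn_spec = preset["binuclear_fraction"]
    binuc = np.clip(rng.normal(bn_spec["mean"], bn_spec["sd"], size=m), 0.0, 0.45)

    configs = []
    for i in range(m):
        p8n = p8[i] * (1 - f16)
        p16n = p8[i] * f16
        p2n = 1.0 - p4[i] - p8n - p16n
        probs = np.array([p2n, p4[i], p8n, p16n])
        probs = probs / probs.sum()
        configs.append(SceneConfig(
            n_cells=int(preset.get("n_cells", 950)),
            binuclear_fraction=float(binuc[i]),
            ploidy_class_probs=tuple(probs),
            mitotic_fraction=float(preset.get("mitotic_fraction", 0.02)),
            seed=int(rng.integers(0, 2**31 - 1)),
        ))
    return configs
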