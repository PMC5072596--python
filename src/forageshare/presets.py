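"""Named scenario presets.

The S1-S7 scenarios are small, watchable configurations spanning the model's
qualitative regimes: lone searchers on slow and fast landscapes, predator
pairs with and without information sharing, and ten-predator groups on rich
patches. They double as quick-start fixtures for the CLI and the examples.
"""

from __future__ import annotations

from forageshare.abm import AbmConfig, SocialNetwork

_BASE = dict(
    domain_size=1.0,
    patch_radius=0.05,
    sensing_radius=0.08,
    speed=1.0,
    consumption_rate=10.0,
    prey_per_patch=20.0,
    turning_rate=6.0,
    dt=0.01,
    n_steps=40_000,
    seed=0,
)

# description strings are shown by `forageshare simulate --list-presets`
PRESETS: dict[str, dict] = {
    "S1": dict(_BASE, n_predators=1, n_patches=10, landscape_rate=0.01,
               _lam=0.0, _doc="1 predator, 10 nearly immobile prey patches"),
    "S2": dict(_BASE, n_predators=1, n_patches=10, landscape_rate=2.0,
               _lam=0.0, _doc="1 predator, 10 frequently moving prey patches"),
    "S3": dict(_BASE, n_predators=2, n_patches=4, landscape_rate=0.05,
               _lam=0.0, _doc="2 predators, no information sharing, slow landscape"),
    "S4": dict(_BASE, n_predators=2, n_patches=4, landscape_rate=0.05,
               _lam=1.0, _doc="2 predators sharing continuously, slow landscape"),
    "S5": dict(_BASE, n_predators=2, n_patches=4, landscape_rate=2.0,
               sensing_radius=0.15, _lam=1.0,
               _doc="2 sharing predators, mobile patches, wide sensing radius"),
    "S6": dict(_BASE, n_predators=10, n_patches=4, landscape_rate=0.05,
               consumption_rate=2.0, _lam=0.0,
               _doc="10 non-sharing predators, slowly consumed patches"),
    "S7": dict(_BASE, n_predators=10, n_patches=4, landscape_rate=0.05,
               consumption_rate=2.0, _lam=1.0,
               _doc="10 sharing predators, slowly consumed patches"),
}


def preset_names() -> list[str]:
    return sorted(PRESETS)


def preset_description(name: str) -> str:
    return PRESETS[name]["_doc"]


def load_preset(name: str, **overrides) -> AbmConfig:
    """Build the named preset configuration, with optional field overrides.

    ``lam`` may be passed as an override to rebuild the (fully connected)
    social network at a different homogeneous tie strength.
    """
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {preset_names()}")
    params = {k: v for k, v in PRESETS[name].items() if not k.startswith("_")}
    lam = overrides.pop("lam", PRESETS[name]["_lam"])
    params.update(overrides)
    n = params["n_predators"]
    params.setdefault("network", SocialNetwork.full(n, float(lam)))
    return AbmConfig(**params)
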