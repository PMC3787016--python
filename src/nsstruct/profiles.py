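"""Pipeline configuration profiles.

A profile carries every stage parameter of the NSS pipeline.  Two presets
mirror the published configurations for the 15-scene and 8-sport datasets;
the ``synthetic`` preset is the desk-scale configuration used with the
built-in synthetic benchmark.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass

import yaml

__all__ = ["PipelineProfile", "get_profile", "PROFILES"]


@dataclass(frozen=True)
class PipelineProfile:
    # sampling
    step: int = 4
    diameters: tuple[int, ...] = (16, 24)
    target_diameter: int = 16
    max_long_edge: int | None = None
    center_patches: bool = True
    # IC basis
    n_ics: int = 160
    ica_patches: int = 20_000
    n_ic_clusters: int = 100
    n_orientation_bins: int = 16
    # codebook
    nss_per_category: int = 1000
    codebook_samples: int = 20_000
    occurrence_threshold: int | None = 7  # M_c; None disables selection
    # spatial
    L_c: int = 3
    N_c: int = 3
    distance_metric: str = "manhattan"
    # classifier
    C: float = 0.125
    kernel_variant: str = "one_minus"
    # numerics
    kmeans_restarts: int = 10
    # ablation switches
    use_scales: tuple[int, ...] | None = None  # None = all scales
    hexagon: bool = True  # False = central circle only
    use_adjacency: bool = True

    def replace(self, **kw) -> "PipelineProfile":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["diameters"] = list(d["diameters"])
        if d["use_scales"] is not None:
            d["use_scales"] = list(d["use_scales"])
        return d

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "PipelineProfile":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineProfile":
        d = dict(d)
        if "diameters" in d:
            d["diameters"] = tuple(d["diameters"])
        if d.get("use_scales") is not None:
            d["use_scales"] = tuple(d["use_scales"])
        return cls(**d)


PROFILES: dict[str, PipelineProfile] = {
    # published 15-scene configuration (paper-scale sample counts noted in docs)
    "scenes15": PipelineProfile(
        step=4, diameters=(16, 24), target_diameter=16, max_long_edge=None,
        n_ics=160, n_ic_clusters=100, nss_per_category=1000,
        occurrence_threshold=7, L_c=3, N_c=3, C=0.125,
    ),
    # published 8-sport configuration: larger images, four scales, no selection
    "sports8": PipelineProfile(
        step=8, diameters=(16, 24, 32, 46), target_diameter=16, max_long_edge=840,
        n_ics=160, n_ic_clusters=40, nss_per_category=600,
        occurrence_threshold=None, L_c=5, N_c=1, C=0.125,
    ),
    # desk-scale profile for the synthetic benchmark (256x256 images)
    "synthetic": PipelineProfile(
        step=8, diameters=(16, 24), target_diameter=16, max_long_edge=None,
        n_ics=48, ica_patches=20_000, n_ic_clusters=24, n_orientation_bins=16,
        nss_per_category=50, codebook_samples=20_000,
        occurrence_threshold=7, L_c=3, N_c=3, C=0.125, kmeans_restarts=3,
    ),
}


def get_profile(name: str, **overrides) -> PipelineProfile:
    """Look up a preset profile by name, optionally overriding fields."""
    if name not in PROFILES:
        raise KeyError(f"unknown profile {name!r}; choose from {sorted(PROFILES)}")
    p = PROFILES[name]
    return p.replace(**overrides) if overrides else p
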