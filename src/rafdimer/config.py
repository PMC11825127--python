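"""Run configuration: every numeric criterion of the pipeline in one record.

Defaults are the criteria used throughout the package: 19.6 Å αC boundary,
140° DFG boundary, 4.0/4.5 Å salt-bridge criteria, 3.5 Å h-bond cutoff,
4.0/4.5 Å hydrophobic cutoffs, 4.5 Å contact cutoff with a 0.7 stable-
contact threshold, 0.3 Å classifier deviation threshold, 40 % trajectory
trim, 50 histogram bins and 4 communities.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

from . import classifier, contact_network, descriptors, fingerprints, trajectory

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    """Configuration failed validation."""


@dataclass
class RunConfig:
    alpha_c_boundary: float = descriptors.ALPHA_C_BOUNDARY
    dfg_boundary: float = descriptors.DFG_BOUNDARY
    salt_bridge_cutoff: float = descriptors.SALT_BRIDGE_NO_CUTOFF
    salt_bridge_sidechain_cutoff: float = descriptors.SALT_BRIDGE_SIDECHAIN_CUTOFF
    hbond_cutoff: float = fingerprints.HBOND_CUTOFF
    hydrophobic_aromatic_cutoff: float = fingerprints.HYDROPHOBIC_AROMATIC_CUTOFF
    hydrophobic_cutoff: float = fingerprints.HYDROPHOBIC_CUTOFF
    contact_cutoff: float = contact_network.CONTACT_CUTOFF
    stable_contact_threshold: float = contact_network.STABLE_CONTACT_THRESHOLD
    classifier_threshold: float = classifier.DEVIATION_THRESHOLD
    trim_fraction: float = trajectory.TRIM_FRACTION
    n_bins: int = trajectory.N_BINS
    n_communities: int = contact_network.N_COMMUNITIES
    seed: int = 0

    def validate(self) -> "RunConfig":
        for name in (
            "alpha_c_boundary",
            "dfg_boundary",
            "salt_bridge_cutoff",
            "salt_bridge_sidechain_cutoff",
            "hbond_cutoff",
            "hydrophobic_aromatic_cutoff",
            "hydrophobic_cutoff",
            "contact_cutoff",
            "classifier_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0.0 <= self.stable_contact_threshold <= 1.0:
            raise ConfigError("stable_contact_threshold must lie in [0, 1]")
        if not 0.0 <= self.trim_fraction < 1.0:
            raise ConfigError("trim_fraction must lie in [0, 1)")
        if self.n_bins < 1 or self.n_communities < 1:
            raise ConfigError("n_bins and n_communities must be ≥ 1")
        return self

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a flat key = value document (TOML) with CLI overrides on top."""
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data).validate()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        """Short stable hash of the configuration, for provenance headers."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]
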