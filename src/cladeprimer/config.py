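"""Run configuration: every pipeline knob in one serializable place.

Defaults reproduce the published design settings: 90% consensus, 15-nt
window with at most 2 degeneracies, 20-30 nt primers, scanning at up to
3 mismatches, 20 hits at an 80% similarity cutoff with the 99->80%
step-wise taxonomy descent, and a 97% OTU cutoff.  The config file is a
flat key: value YAML document; CLI flags override config values.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml


@dataclass
class RunConfig:
    # consensus
    consensus_threshold: float = 0.90
    consensus_method: str = "minimal-set"
    max_gap_fraction: float = 0.5
    # windows / candidates
    window_length: int = 15
    window_max_degeneracies: int = 2
    primer_min_len: int = 20
    primer_max_len: int = 30
    primer_max_degeneracies: int = 2
    # scanning / pair selection
    max_mismatches: int = 3
    mismatch_mode: str = "per-primer"
    mm_sel: int = 1
    mm_spec: int = 2
    lam: float = 1.0
    min_amplicon: int = 50
    max_amplicon: int = 2000
    pair_top_n: int = 40
    # classification
    classify_k: int = 20
    classify_cutoff_pct: float = 80.0
    taxonomy_start_pct: float = 99.0
    taxonomy_floor_pct: float = 80.0
    taxonomy_step: float = 1.0
    # OTUs / rarefaction
    otu_cutoff_pct: float = 97.0
    rarefaction_replicates: int = 1000
    # randomness
    seed: int = 0

    def validate(self) -> "RunConfig":
        if not 0.5 < self.consensus_threshold <= 1.0:
            raise ValueError("consensus_threshold must be in (0.5, 1.0]")
        if self.consensus_method not in ("minimal-set", "inclusion"):
            raise ValueError("consensus_method must be minimal-set or inclusion")
        if not 0.0 <= self.max_gap_fraction <= 1.0:
            raise ValueError("max_gap_fraction must be in [0, 1]")
        if self.window_length < 1 or self.window_max_degeneracies < 0:
            raise ValueError("bad window spec")
        if not 1 <= self.primer_min_len <= self.primer_max_len:
            raise ValueError("bad primer length bounds")
        if self.max_mismatches < 0 or self.mm_sel < 0 or self.mm_spec < 0:
            raise ValueError("mismatch allowances must be >= 0")
        if self.mismatch_mode not in ("per-primer", "summed"):
            raise ValueError("mismatch_mode must be per-primer or summed")
        if not 0 < self.min_amplicon <= self.max_amplicon:
            raise ValueError("bad amplicon bounds")
        if self.classify_k < 1:
            raise ValueError("classify_k must be >= 1")
        if not (
            0 <= self.taxonomy_floor_pct <= self.taxonomy_start_pct <= 100
            and self.taxonomy_step > 0
        ):
            raise ValueError("bad taxonomy thresholds")
        if not 0 < self.otu_cutoff_pct <= 100:
            raise ValueError("otu_cutoff_pct must be in (0, 100]")
        if self.rarefaction_replicates < 1:
            raise ValueError("rarefaction_replicates must be >= 1")
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a flat key: value mapping")
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"{path}: unknown config keys {unknown}")
        return cls(**raw).validate()

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
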