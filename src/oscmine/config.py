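"""Mining configuration: every threshold of the filter cascade in one place."""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass

import yaml


@dataclass
class MiningConfig:
    """Thresholds and tunables for the mining pipeline.

    Defaults are the pipeline's standard operating point: pass-1 keeps
    loci with protein length > 40 aa OR profile coverage > 0.3; the refilter
    requires average weighted sequence identity (AWSI) >= 0.2; spliced models
    must reach the spliced-score floor and E-value < 1e-5; high-quality
    proteins are >= 650 aa, non-pseudogene, and reach bitscore > 500 or pass
    the whole cascade.  Introns are GT..AG, 40 nt to 20 kb.
    """

    min_protein_aa_pass1: int = 40
    min_coverage_pass1: float = 0.3
    min_awsi: float = 0.2
    #: floor on the spliced alignment score, in bits.  Stands in for the
    #: protein-to-genome aligner's raw score threshold of 300, whose scale is
    #: tool-internal; see docs/methods.md.
    min_spliced_score: float = 100.0
    #: models below this spliced score are not reported at all (candidates
    #: between the report floor and min_spliced_score fail the score filter)
    report_floor_bits: float = 20.0
    max_intron: int = 20000
    min_intron: int = 40
    max_evalue: float = 1e-5
    hq_min_len: int = 650
    hq_min_bitscore: float = 500.0
    profiling_min_span: int = 450
    bloom_mean_copies: float = 4.0
    seed_window_codons: int = 30
    #: chance 30-codon windows against a ~700-column profile reach ~13-16
    #: bits; the threshold sits above that tail so unrelated loci are never
    #: chained through background windows
    seed_min_bits: float = 20.0
    locus_flank: int = 20000
    rng_seed: int = 0
    # scoring penalties (bits)
    intron_open_bits: float = -8.0
    frameshift_bits: float = -15.0
    stop_bits: float = -20.0
    # behaviour switches
    awsi_strict: bool = False          # strict ( > ) instead of inclusive ( >= )
    ambiguity_margin_bits: float = 1.0
    max_models_per_locus: int = 6
    calibration_decoys: int = 200
    calibration_decoy_len: int = 720

    def __post_init__(self):
        if self.max_intron < self.min_intron:
            raise ValueError("max_intron must be >= min_intron")
        for name in ("min_protein_aa_pass1", "min_coverage_pass1", "min_awsi",
                     "min_spliced_score", "max_intron", "min_intron", "max_evalue",
                     "hq_min_len", "hq_min_bitscore", "profiling_min_span",
                     "bloom_mean_copies", "seed_window_codons", "locus_flank"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class ConfigError(ValueError):
    pass


def load_config(path=None, overrides: dict | None = None) -> MiningConfig:
    """Load a flat key/value YAML config; unspecified keys take the defaults.

    Unknown keys raise ConfigError naming the key (typo guard).  ``overrides``
    (e.g. from CLI flags) take precedence over the file.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: config must be a flat mapping")
        data.update(loaded)
    if overrides:
        data.update(overrides)
    valid = {f.name for f in dataclasses.fields(MiningConfig)}
    unknown = sorted(set(data) - valid)
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(unknown)}")
    try:
        return MiningConfig(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
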