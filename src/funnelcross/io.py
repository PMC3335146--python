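"""File formats, run configuration and the end-to-end pipeline.

VCF v4.2 carries genotype panels: "|"-separated GT fields yield phased
haplotypes, "/" yields an unphased matrix, "." is missing.  Maps travel as
TSV (chrom, id, bp, cM; 1-based bp, cM cumulative from the chromosome
start).  Result writers embed the seed and a config digest so artifacts
are traceable to the run that produced them.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .core import GeneticMap, read_map_tsv, rng_stream
from .diversity import MISSING, GenotypeMatrix

logger = logging.getLogger("funnelcross")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

@dataclass
class VcfData:
    """Parsed VCF: unphased dosage matrix plus haplotypes when phased."""

    matrix: GenotypeMatrix
    haplotypes: Optional[np.ndarray]  # (2n, L) or None when any "/" call
    phased: bool


def read_vcf(path) -> VcfData:
    """Read a diploid VCF v4.2 with cyvcf2.

    Fully "|"-phased files also return the (2n, L) haplotype array;
    mixed or unphased files return the dosage matrix only.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    calls = []
    hap_a = []
    hap_b = []
    all_phased = True
    for variant in vcf:
        rows.append({"chrom": variant.CHROM, "id": variant.ID or ".",
                     "bp": variant.POS})
        col = np.empty(len(samples), dtype=np.int8)
        ca = np.empty(len(samples), dtype=np.int8)
        cb = np.empty(len(samples), dtype=np.int8)
        for i, g in enumerate(variant.genotypes):
            a, b, phased = g[0], g[1], bool(g[-1])
            if a < 0 or b < 0:
                col[i] = MISSING
                ca[i] = cb[i] = MISSING
            else:
                if a > 1 or b > 1:
                    raise ValueError(
                        f"non-biallelic GT at {variant.CHROM}:{variant.POS}")
                col[i] = a + b
                ca[i], cb[i] = a, b
            if not phased and a >= 0 and b >= 0:
                # missing calls carry no phase information and do not
                # demote an otherwise phased panel
                all_phased = False
        calls.append(col)
        hap_a.append(ca)
        hap_b.append(cb)
    if not rows:
        raise ValueError(f"no variant records in {path}")
    markers = pd.DataFrame(rows)
    matrix = GenotypeMatrix(calls=np.stack(calls, axis=1), markers=markers,
                            samples=samples)
    haps = None
    if all_phased:
        ha = np.stack(hap_a, axis=1)
        hb = np.stack(hap_b, axis=1)
        haps = np.empty((2 * len(samples), len(rows)), dtype=np.int8)
        haps[0::2] = ha
        haps[1::2] = hb
    return VcfData(matrix=matrix, haplotypes=haps, phased=all_phased)


def write_vcf(path, markers: pd.DataFrame, samples: list,
              calls: Optional[np.ndarray] = None,
              haplotypes: Optional[np.ndarray] = None) -> None:
    """Write a minimal biallelic VCF v4.2.

    Pass either haplotypes (2n, L) for phased "|" output or calls (n, L)
    dosages for unphased "/" output.
    """
    if (calls is None) == (haplotypes is None):
        raise ValueError("pass exactly one of calls or haplotypes")
    lines = ["##fileformat=VCFv4.2",
             "##source=funnelcross",
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
             "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
             + "\t".join(samples)]
    n = len(samples)
    for j, row in markers.reset_index(drop=True).iterrows():
        gts = []
        for i in range(n):
            if haplotypes is not None:
                a, b = haplotypes[2 * i, j], haplotypes[2 * i + 1, j]
                if a == MISSING or b == MISSING:
                    gts.append(".|.")
                else:
                    gts.append(f"{a}|{b}")
            else:
                c = calls[i, j]
                if c == MISSING:
                    gts.append("./.")
                else:
                    gts.append({0: "0/0", 1: "0/1", 2: "1/1"}[int(c)])
        lines.append(
            f"{row['chrom']}\t{row['bp']}\t{row['id']}\tA\tT\t.\tPASS\t.\tGT\t"
            + "\t".join(gts))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Result writers
# ---------------------------------------------------------------------------

def _config_digest(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_results(results, path, fmt: str = "tsv", seed: Optional[int] = None,
                  config: Optional[dict] = None) -> None:
    """Serialize a DataFrame (tsv) or mapping (json) with run metadata.

    Column order is deterministic; floats carry 6 significant digits; the
    seed and a config digest ride along as comment lines / a _meta block.
    """
    meta = {"seed": seed,
            "config_digest": _config_digest(config or {})}
    path = Path(path)
    if fmt == "tsv":
        if not isinstance(results, pd.DataFrame):
            results = pd.DataFrame(results)
        header = "".join(f"#{k}={v}\n" for k, v in meta.items())
        body = results.to_csv(sep="\t", index=False, float_format="%.6g")
        path.write_text(header + body)
    elif fmt == "json":
        payload = {"_meta": meta}
        if isinstance(results, pd.DataFrame):
            payload["records"] = json.loads(
                results.to_json(orient="records", double_precision=6))
        else:
            payload.update(_jsonify(results))
        path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    else:
        raise ValueError("format must be 'tsv' or 'json'")


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        return float(f"{float(obj):.6g}")
    return obj


def read_results_json(path) -> dict:
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Parameters of one reproducible pipeline run."""

    seed: int = 1
    out_dir: str = "funnelcross_out"
    log_level: str = "INFO"
    # synthetic-data scale
    n_snps_iv: int = 179
    n_snps_x: int = 199
    n_isolates: int = 16
    n_distinct_genotypes: int = 14
    sample_individuals: int = 89
    missing_rate: float = 0.02
    # simulation scale
    n_sims: int = 100
    expansion_size: int = 1000
    expansion_generations: int = 3
    # selection inference
    true_s: float = 0.53
    sims_per_point: int = 40
    n_reps: int = 10
    # windowed statistics
    window_width: int = 10
    n_permutations: int = 200
    envelope_level: float = 0.95
    maf_threshold: float = 0.05
    lost_threshold: float = 0.026
    # outcrossing
    true_male_frequency: float = 0.196
    detection: float = 0.74
    n_plates: int = 12

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def pipeline_run(config: RunConfig) -> int:
    """synth -> simulate -> estimate-s -> windowed stats -> outcross.

    Writes per-stage artifacts under config.out_dir; a stage failure
    raises after logging the stage name, leaving earlier artifacts behind.
    """
    from . import derivation, diversity, inference, mating, synth

    logging.basicConfig(level=getattr(logging, config.log_level.upper()))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = asdict(config)
    stage = "synth"
    try:
        rng = rng_stream(config.seed, "synth")
        maps = {
            "IV": synth.make_map(synth.DomainMapSpec(), config.n_snps_iv, rng),
            "X": synth.make_map(synth.x_map_spec(), config.n_snps_x, rng),
        }
        pd.concat([m.to_frame() for m in maps.values()]).to_csv(
            out / "map.tsv", sep="\t", index=False)
        panel_spec = synth.PanelSpec(
            n_isolates=config.n_isolates,
            n_distinct_genotypes=config.n_distinct_genotypes)
        parents, truth = synth.make_parental_panel(panel_spec, maps, rng)
        write_results(truth, out / "panel_truth.json", "json",
                      seed=config.seed, config=cfg)
        logger.info("stage synth done")

        stage = "simulate"
        design = derivation.FunnelDesign(
            expansion_size=config.expansion_size,
            expansion_generations=config.expansion_generations)
        rng = rng_stream(config.seed, "simulate")
        freqs, pools = derivation.simulate_funnel(
            design, parents, maps, None, config.n_sims, rng,
            return_pools=True)
        env_rows = []
        for chrom, gmap in maps.items():
            env = derivation.neutral_envelope(freqs[chrom],
                                              config.envelope_level)
            obs = freqs[chrom][0]
            flags, _ = derivation.classify_deviants(obs, env)
            env_rows.append(pd.DataFrame({
                "chrom": chrom, "id": gmap.marker_ids,
                "bp": gmap.positions_bp, "lower": env.lower,
                "upper": env.upper, "observed": obs,
                "deviant_flag": flags.astype(int)}))
        write_results(pd.concat(env_rows, ignore_index=True),
                      out / "envelope.tsv", "tsv", seed=config.seed,
                      config=cfg)
        logger.info("stage simulate done")

        stage = "estimate-s"
        def obs_source(r):
            return inference.simulate_observation(
                design, config.true_s, r,
                n_individuals=config.sample_individuals)
        mean_s, sd_s, est = inference.replicate_estimates(
            obs_source, 2 * config.sample_individuals, design,
            seed=config.seed, n_reps=config.n_reps,
            sims_per_point=config.sims_per_point)
        write_results({"mean_s": mean_s, "sd_s": sd_s,
                       "estimates": est, "true_s": config.true_s},
                      out / "mle.json", "json", seed=config.seed, config=cfg)
        logger.info("stage estimate-s done: mean_s=%.3f", mean_s)

        stage = "stats"
        rng = rng_stream(config.seed, "stats")
        hap_pools = [pools[0], pools[1]]
        stats_rows = []
        for chrom, gmap in maps.items():
            ha = hap_pools[0].haps[chrom].reshape(-1, gmap.n_markers)
            hb = hap_pools[1].haps[chrom].reshape(-1, gmap.n_markers)
            counts = diversity.window_haplotype_count(
                ha, gmap.positions_bp, config.window_width)
            fst = diversity.fst_window(ha, hb, gmap.positions_bp,
                                       config.window_width)
            thr = diversity.fst_permutation_threshold(
                ha, hb, config.window_width, rng,
                n_perm=config.n_permutations, level=config.envelope_level)
            counts["chrom"] = chrom
            counts["fst"] = fst["value"]
            counts["fst_threshold"] = thr
            stats_rows.append(counts)
        write_results(pd.concat(stats_rows, ignore_index=True),
                      out / "windows.tsv", "tsv", seed=config.seed,
                      config=cfg)
        logger.info("stage stats done")

        stage = "outcross"
        rng = rng_stream(config.seed, "outcross")
        census = synth.make_census(config.true_male_frequency,
                                   config.detection, config.n_plates, rng)
        census.to_csv(out / "census.tsv", sep="\t", index=False)
        kept = mating.plate_qc(census)
        c = config.detection
        estimate = mating.estimate_outcrossing(kept, correction=c)
        write_results(asdict(estimate), out / "outcrossing.json", "json",
                      seed=config.seed, config=cfg)
        logger.info("stage outcross done")
    except Exception:
        logger.exception("pipeline failed at stage %s", stage)
        raise
    return 0
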