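"""Reference evaluation scenarios.

These runners re-create the package's headline validation experiments from
scratch -- published-scale copy-number arithmetic, copy-number recovery on a
synthetic 20-Mb genome, arrangement typing of the archetype bundles, and
heterogeneity discrimination -- so that the test suite and the acceptance
script exercise identical study conditions.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np

from rdnakit import graph_cluster, quantify_map, simulate
from rdnakit.archetypes import make_canonical_genes, make_simple_5s_unit
from rdnakit.cli_report import PipelineConfig, generate_fixtures, run_pipeline
from rdnakit.quantify_map import estimate_copy_number
from rdnakit.simulate import ArraySpec, PseudogeneEvent, ReadSimSpec, SyntheticGenomeSpec


def published_copy_numbers() -> dict[str, float]:
    """Copy numbers recomputed from published GP values (CN = GP x G / L).

    Keys name the species and gene family; GP values are the published
    genome proportions, genome sizes are 1C values in bp, reference lengths
    are the trimmed gene references (1800-bp 18S, 120-bp 5S).
    """
    return {
        # (gp, genome size bp, reference length bp)
        "cn_18s_ephedra_altissima": estimate_copy_number(0.00058, 18.5e9, 1800),
        "cn_18s_gnetum_montanum": estimate_copy_number(0.00132, 4.2e9, 1800),
        "cn_18s_welwitschia_mirabilis": estimate_copy_number(0.00063, 7.2e9, 1800),
        "cn_5s_gnetum_montanum": estimate_copy_number(0.00301, 4.2e9, 120),
    }


def published_ratio_claims() -> dict[str, float]:
    """Fold-ranges and bound claims recomputed from published copy numbers."""
    return {
        # 18S CN range 2500..6000 (>2-fold); 5S CN range 3900..105200 (27-fold)
        "fold_range_18s_cn": 6000 / 2500,
        "fold_range_5s_cn": 105_200 / 3_900,
        # G. montanum 5S vs E. altissima 5S ("seven times more copies")
        "gnetum_vs_ephedra_5s_fold": 105_200 / 15_000,
        # StuI fragments 22 kb (26S probe) + 4 kb (5S probe) -> unit >= 26 kb
        "linked_unit_min_size_kb": 22.0 + 4.0,
        # 2.8 copies of a 71-bp subrepeat inside a 1160-bp ITS1 (< 20 %)
        "its1_subrepeat_fraction_pct": 100.0 * 2.8 * 71 / 1160,
    }


# --------------------------------------------------------------------------
# Copy-number recovery on a synthetic genome


def cn_recovery_scenario(
    seed: int, coverage: float, genome_size: int = 20_000_000, n_copies: int = 1000
) -> quantify_map.CopyNumberEstimate:
    """Plant a 700-bp 5S unit ``n_copies`` times in ``genome_size`` bp,
    sequence at ``coverage`` (90-bp pairs, 0.3 % error) and re-estimate the
    copy number against the 120-bp gene reference."""
    rng = np.random.default_rng(seed)
    canonical = make_canonical_genes(rng)
    unit = make_simple_5s_unit("sim5S", canonical, rng, nts_length=580)
    genome, _ = simulate.plant_arrays(
        SyntheticGenomeSpec(
            genome_size=genome_size, arrays=(ArraySpec(unit, n_copies),), seed=seed
        )
    )
    pairs = simulate.simulate_reads(
        genome,
        ReadSimSpec(coverage=coverage, read_length=90, insert_size=300,
                    error_rate=0.003, seed=seed + 1),
    )
    reads = {}
    for p in pairs:
        reads[p.name + "/1"] = p.seq1
        reads[p.name + "/2"] = p.seq2
    recs = quantify_map.map_reads(
        reads, ("5S", canonical["5S"]), min_identity=90, min_read_fraction=0.5
    )
    return quantify_map.CopyNumberEstimate.from_counts(
        len(recs), len(reads), genome_size, 120
    )


# --------------------------------------------------------------------------
# Arrangement typing


def arrangement_trial(seed: int, work_dir: str | Path | None = None) -> dict[str, dict]:
    """Generate the L-type and S-type bundles for ``seed``, run the full
    pipeline on each, and report all three evidence channels."""
    results: dict[str, dict] = {}
    with tempfile.TemporaryDirectory() as tmp:
        base = Path(work_dir) if work_dir is not None else Path(tmp)
        bundles = generate_fixtures(base / f"seed{seed}", seed=seed)
        for name in ("l_homogeneous", "s_heterogeneous"):
            cfg = PipelineConfig.from_yaml(bundles[name] / "config.yaml")
            cfg.out_dir = str(bundles[name] / "pipeline_out")
            report = run_pipeline(cfg)
            results[name] = {
                "call": report.arrangement_call,
                "co_cluster": report.linkage["co_cluster"],
                "cross_mate_fraction": report.linkage["cross_mate_fraction"],
                "digest_cohybridization": report.digest_cohybridization,
            }
    return results


def arrangement_channels_correct(results: dict[str, dict]) -> bool:
    """True iff both bundles are typed correctly by every evidence channel."""
    l, s = results["l_homogeneous"], results["s_heterogeneous"]
    return (
        l["call"] == "L"
        and l["co_cluster"]
        and l["cross_mate_fraction"] >= 0.05
        and l["digest_cohybridization"]
        and s["call"] == "S"
        and not s["co_cluster"]
        and s["cross_mate_fraction"] < 0.05
        and not s["digest_cohybridization"]
    )


# --------------------------------------------------------------------------
# Heterogeneity discrimination


def heterogeneity_trial(seed: int) -> tuple[float, float]:
    """Mean pairwise read identity over a homogeneous (rate 0) and a
    heterogeneous (rate 0.05) array built from the same 700-bp unit."""
    rng = np.random.default_rng(seed)
    canonical = make_canonical_genes(rng)
    unit = make_simple_5s_unit("u", canonical, rng, nts_length=580)
    means = []
    for rate in (0.0, 0.05):
        seq, _ = simulate.build_array(
            ArraySpec(unit, n_copies=15, per_copy_sub_rate=rate),
            np.random.default_rng(seed + 1),
        )
        pairs = simulate.simulate_reads(
            seq,
            ReadSimSpec(coverage=0.6, read_length=90, insert_size=170,
                        error_rate=0.003, seed=seed + 2),
        )
        reads = {p.name + "/1": p.seq1 for p in pairs[:40]}
        means.append(graph_cluster.mean_pair_identity(reads))
    return means[0], means[1]


def snp_density_trial(seed: int) -> tuple[float, float]:
    """SNPs/kb in a clean 5S gene vs an NTS spacer diverged at 5 % in half
    of the array copies (shared haplotype, so alleles sit near 50 %)."""
    rng = np.random.default_rng(seed)
    canonical = make_canonical_genes(rng)
    unit = make_simple_5s_unit("u", canonical, rng, nts_length=580)
    seq, _ = simulate.build_array(
        ArraySpec(
            unit,
            n_copies=40,
            per_copy_sub_rate=0.002,
            pseudogene_events=(PseudogeneEvent("NTS", 0, 0.05),),
        ),
        np.random.default_rng(seed + 1),
    )
    pairs = simulate.simulate_reads(
        seq,
        ReadSimSpec(coverage=6.0, read_length=90, insert_size=170,
                    error_rate=0.003, seed=seed + 2),
    )
    reads = {}
    for p in pairs:
        reads[p.name + "/1"] = p.seq1
        reads[p.name + "/2"] = p.seq2
    recs = quantify_map.map_reads(reads, unit, min_read_fraction=0.5)
    pile = quantify_map.build_pileup(recs, unit)
    snps = quantify_map.call_snps(pile, unit)
    dens = quantify_map.snp_density_by_subregion(snps, unit).set_index("label")
    return float(dens.loc["5S", "snps_per_kb"]), float(dens.loc["NTS", "snps_per_kb"])
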