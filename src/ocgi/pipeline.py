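"""Config-driven end-to-end run on synthetic data.

One YAML config drives simulate -> call -> filter -> orthology ->
peak/grid tests -> shuffle test -> HGE test -> expression test, writing
every stage's outputs plus a machine-readable manifest (inputs,
parameters, seed and output checksums) into an append-only run
directory. Re-running the same config reproduces identical checksums
for every deterministic stage, because every stochastic stage is seeded
from the config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import __version__
from .caller import CgiParams, call_genome, calls_to_table
from .enrichment import shuffle_test
from .expression import (
    assign_gene_sets,
    compute_tpm,
    expression_ratio_test,
    genes_to_table,
    great_domains,
)
from .filtering import cross_species_filter, filter_orphan
from .hge import matched_resample_test
from .intervals import FeatureCategory, FeatureSet, write_bed
from .orthology import build_orthologous_sites, map_interval, sites_to_table
from .simulate import (
    SyntheticSpec,
    make_enhancers,
    make_expression,
    make_gene_layout,
    make_peaks_and_signal,
    make_species_pair,
)
from .turnover import label_sites, permutation_grid_test

__all__ = ["load_config", "run_pipeline"]

_TEST_DEFAULTS = {
    "grid_rounds": 1000,
    "shuffle_rounds": 200,
    "expr_rounds": 1000,
    "hge_rounds": 1000,
    "bins": 10,
    "min_oe_delta": 0.0,
}

_SPEC_FIELDS = {f.name for f in dataclasses.fields(SyntheticSpec)}


def load_config(path_or_dict) -> dict:
    """Load and validate a run config.

    Schema: top-level keys ``spec`` (SyntheticSpec fields) and optional
    ``tests`` (round/bin counts). Unknown keys fail before any stage
    runs, naming the offending key.
    """
    if isinstance(path_or_dict, Mapping):
        raw = dict(path_or_dict)
    else:
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "spec" not in raw:
        raise ValueError("config must be a mapping with a 'spec' section")
    unknown_top = set(raw) - {"spec", "tests"}
    if unknown_top:
        raise ValueError(f"unknown config section(s): {sorted(unknown_top)}")
    spec_cfg = dict(raw["spec"] or {})
    unknown = set(spec_cfg) - _SPEC_FIELDS
    if unknown:
        raise ValueError(f"unknown spec key(s): {sorted(unknown)}")
    for key in ("turnover_fractions", "peak_base_probs"):
        if key in spec_cfg:
            spec_cfg[key] = tuple(spec_cfg[key])
    tests = dict(_TEST_DEFAULTS)
    extra = set(raw.get("tests") or {}) - set(_TEST_DEFAULTS)
    if extra:
        raise ValueError(f"unknown tests key(s): {sorted(extra)}")
    tests.update(raw.get("tests") or {})
    # SyntheticSpec.__post_init__ validates the numbers themselves
    return {"spec": SyntheticSpec(**spec_cfg), "tests": tests}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_fasta(seqs: dict[str, str], path: Path) -> None:
    with open(path, "w") as fh:
        for chrom, seq in seqs.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def run_pipeline(config, outdir: str | Path) -> dict:
    """Execute the full synthetic study; returns the manifest dict.

    ``config`` is a YAML path or mapping (see :func:`load_config`).
    The run directory is append-only: stages never mutate another
    stage's outputs.
    """
    cfg = load_config(config)
    spec: SyntheticSpec = cfg["spec"]
    tests = cfg["tests"]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": spec.seed,
        "spec": dataclasses.asdict(spec),
        "tests": tests,
        "stages": {},
    }

    def record(stage: str, files: dict[str, Path], params: dict | None = None) -> None:
        manifest["stages"][stage] = {
            "params": params or {},
            "outputs": {k: {"path": str(p.name), "sha256": _sha256(p)} for k, p in files.items()},
        }

    # -- 1. simulate ------------------------------------------------------
    pair = make_species_pair(spec)
    files = {}
    for name, seqs in (("human", pair.human), ("speciesA", pair.seq_A), ("speciesB", pair.seq_B)):
        p = outdir / f"{name}.fa"
        _write_fasta(seqs, p)
        files[name] = p
    p = outdir / "map_A_to_human.tsv"
    pair.map_A_to_human.write_tsv(p)
    files["map_A"] = p
    p = outdir / "map_B_to_human.tsv"
    pair.map_B_to_human.write_tsv(p)
    files["map_B"] = p
    p = outdir / "truth_islands_human.bed"
    write_bed(
        [
            dataclasses.replace(iv, name=f"{iv.name}|{lab}")
            for iv, lab in zip(pair.islands_human, pair.labels)
        ],
        p,
        dialect="bed4",
    )
    files["truth_islands"] = p
    record("simulate", files)

    # -- 2. call ----------------------------------------------------------
    params = CgiParams()
    calls_A = call_genome(pair.seq_A, params)
    calls_B = call_genome(pair.seq_B, params)
    files = {}
    for tag, calls in (("A", calls_A), ("B", calls_B)):
        p = outdir / f"cgi_{tag}.tsv"
        calls_to_table(calls).to_csv(p, sep="\t", index=False)
        files[tag] = p
    record("call", files, dataclasses.asdict(params))

    # -- 3. filter --------------------------------------------------------
    # synthetic genomes carry no gene annotation; the exclusion feature
    # sets are empty and the cross-species step enforces mappability
    empty = [FeatureSet(FeatureCategory.exon), FeatureSet(FeatureCategory.tss)]
    ocgis_A = cross_species_filter(filter_orphan(calls_A, empty), pair.map_A_to_human, [])
    ocgis_B = cross_species_filter(filter_orphan(calls_B, empty), pair.map_B_to_human, [])
    files = {}
    for tag, ocgis in (("A", ocgis_A), ("B", ocgis_B)):
        p = outdir / f"ocgi_{tag}.tsv"
        calls_to_table(ocgis).to_csv(p, sep="\t", index=False)
        files[tag] = p
    record("filter", files)

    # -- 4. orthology -----------------------------------------------------
    sites = build_orthologous_sites(
        ocgis_A, ocgis_B, pair.map_A_to_human, pair.map_B_to_human,
        seqs_A=pair.seq_A, seqs_B=pair.seq_B,
    )
    p = outdir / "sites.tsv"
    sites_to_table(sites).to_csv(p, sep="\t", index=False)
    record("orthology", {"sites": p})

    # -- 5. peaks + grid test --------------------------------------------
    rng = np.random.default_rng(spec.seed + 10)
    peak_data = make_peaks_and_signal(
        spec, sites, pair.chrom_sizes_A, pair.chrom_sizes_B, rng=rng
    )
    labeled = label_sites(sites, peak_data.peaks_A, peak_data.peaks_B)
    grid = permutation_grid_test(
        labeled, rounds=tests["grid_rounds"], seed=spec.seed + 11
    )
    files = {}
    for tag, peaks in (("A", peak_data.peaks_A), ("B", peak_data.peaks_B)):
        p = outdir / f"peaks_{tag}.bed"
        write_bed(
            [dataclasses.replace(pk.interval, score=pk.signal) for pk in peaks],
            p,
            dialect="bed6",
        )
        files[tag] = p
    p = outdir / "grid.json"
    with open(p, "w") as fh:
        json.dump(grid.as_dict(), fh, indent=1)
    files["grid"] = p
    record("grid_test", files, {"rounds": tests["grid_rounds"]})

    # -- 6. shuffle test --------------------------------------------------
    excluded = [
        iv for iv in (map_interval(m, pair.map_A_to_human.invert()) for m in pair.masked_human)
        if iv is not None
    ]
    shuffle = shuffle_test(
        ocgis_A,
        peak_data.peaks_A,
        pair.chrom_sizes_A,
        excluded,
        map_to_human=pair.map_A_to_human,
        human_exclude=[],
        rounds=tests["shuffle_rounds"],
        seed=spec.seed + 12,
    )
    p = outdir / "shuffle.json"
    with open(p, "w") as fh:
        json.dump(shuffle.as_dict(), fh, indent=1)
    record("shuffle_test", {"shuffle": p}, {"rounds": tests["shuffle_rounds"]})

    # -- 7. expression ----------------------------------------------------
    placements, truth, qsites = make_gene_layout(
        spec, pair.chrom_sizes_A, rng=np.random.default_rng(spec.seed + 13)
    )
    genes = make_expression(
        spec, truth, placements, rng=np.random.default_rng(spec.seed + 14)
    )
    domains = great_domains(genes, pair.chrom_sizes_A)
    assignments = assign_gene_sets(domains, qsites)
    tpm_A = compute_tpm(genes, "A")
    tpm_B = compute_tpm(genes, "B")
    expr = expression_ratio_test(
        assignments, tpm_A, tpm_B,
        rounds=tests["expr_rounds"], n_bins=tests["bins"], seed=spec.seed + 15,
    )
    files = {}
    p = outdir / "genes.tsv"
    genes_to_table(genes, p)
    files["genes"] = p
    p = outdir / "expression.json"
    with open(p, "w") as fh:
        json.dump({k: v.as_dict() for k, v in expr.items()}, fh, indent=1)
    files["expression"] = p
    record("expression_test", files, {"rounds": tests["expr_rounds"], "bins": tests["bins"]})

    # -- 8. HGE test ------------------------------------------------------
    hges, background = make_enhancers(spec, rng=np.random.default_rng(spec.seed + 16))
    hge_res = matched_resample_test(
        hges, background, n_bins=tests["bins"], rounds=tests["hge_rounds"],
        seed=spec.seed + 17,
    )
    p = outdir / "hge.json"
    with open(p, "w") as fh:
        json.dump(hge_res.as_dict(), fh, indent=1)
    record("hge_test", {"hge": p}, {"rounds": tests["hge_rounds"], "bins": tests["bins"]})

    p = outdir / "manifest.json"
    with open(p, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
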