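"""End-to-end orchestration: simulate -> phase -> optimize -> build-ref ->
impute -> verify, with a checksummed artifact manifest.

Each stage writes its outputs under the configured directory and registers
them in the manifest; at the end every registered file is re-hashed to
assert that no later stage mutated an earlier stage's output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import io as msio
from .config import RunConfig
from .impute import StrategyConfig, impute_cohort, results_to_frame, score_concordance
from .panel import build_table, summarize_panel
from .parentage import reports_to_frame, verify_cohort
from .phasing import make_window, phase_window, write_phased
from .sim import SimConfig, holdout_split, simulate_panel
from .types import build_region
from .window_opt import optimize_window

log = logging.getLogger("msimpute")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class Manifest:
    files: dict[str, str] = field(default_factory=dict)  # path -> sha256

    def register(self, path: Path) -> None:
        self.files[str(path)] = _sha256(path)

    def verify(self) -> None:
        for path, digest in self.files.items():
            if _sha256(Path(path)) != digest:
                raise StageError(f"manifest: {path} was mutated after creation")

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.files, fh, indent=1, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Manifest:
    """Run all stages on a simulated dataset; returns the artifact manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = Manifest()
    config.to_yaml(out / "run_config.yaml")
    manifest.register(out / "run_config.yaml")

    stage = "simulate"
    try:
        sim_cfg = SimConfig(
            markers=tuple(config.simulate.markers),
            seed=config.seed,
            **config.simulate.model_dump(exclude={"markers"}),
        )
        data = simulate_panel(sim_cfg)
        msio.write_ab_matrix(data.matrix, out / "snp_genotypes.tsv")
        msio.write_ms_genotypes(data.ms_records, out / "ms_genotypes.tsv")
        msio.write_pedigree(data.pedigree, out / "pedigree.tsv")
        msio.write_snp_map(data.snp_map, out / "snp_map.tsv")
        for name in ("snp_genotypes.tsv", "ms_genotypes.tsv", "pedigree.tsv", "snp_map.tsv"):
            manifest.register(out / name)
        log.info("simulate: %d animals, %d markers", len(data.matrix.animal_ids), len(sim_cfg.markers))

        stage = "holdout"
        split = holdout_split(data, "random", config.holdout_fraction, seed=config.seed)
        ref_matrix = data.matrix.subset(split.reference_ids)
        val_matrix = data.matrix.subset(split.validation_ids)
        breeds = data.breeds

        tables = {}
        stage = "phase/optimize/build-ref"
        for marker in data.ms_map:
            region = build_region(marker, data.snp_map, config.flank_bp)

            def provider(size: int, _region=region):
                return phase_window(
                    ref_matrix,
                    make_window(_region, size),
                    pedigree=data.pedigree,
                    seed=config.seed,
                    max_iter=config.phaser_iterations,
                    restarts=config.phaser_restarts,
                    ms=split.reference_ms,
                )

            sizes = sorted({min(s, len(region.snps)) for s in config.window_sizes})
            trace = optimize_window(
                marker.name,
                provider,
                sizes=sizes,
                breeds=breeds,
                min_count=config.min_count,
                concordance=config.concordance,
                plateau_tol=config.plateau_tol,
            )
            haps = provider(trace.chosen_size)
            write_phased(haps, out / f"{marker.name}.phased.tsv")
            manifest.register(out / f"{marker.name}.phased.tsv")
            table = build_table(haps, breeds, config.min_count, config.concordance)
            tables[marker.name] = table
            table.to_frame().to_csv(out / f"{marker.name}.assoc.tsv", sep="\t", index=False)
            manifest.register(out / f"{marker.name}.assoc.tsv")
            trace_json = {
                "marker": trace.marker,
                "candidate_sizes": trace.candidate_sizes,
                "chosen_size": trace.chosen_size,
                "stop_reason": trace.stop_reason,
                "tallies": [vars(t) for t in trace.tallies],
            }
            (out / f"{marker.name}.trace.json").write_text(json.dumps(trace_json, indent=1))
            manifest.register(out / f"{marker.name}.trace.json")

        summary = summarize_panel(list(tables.values()))
        summary.per_marker.to_csv(out / "panel_summary.tsv", sep="\t", index=False)
        manifest.register(out / "panel_summary.tsv")

        stage = "impute"
        strategy = StrategyConfig(
            reference_taxon=config.taxon,
            iterations=config.phaser_iterations,
            restarts=config.phaser_restarts,
            seed=config.seed,
            allow_ambiguous=config.allow_ambiguous,
            backoff_floor=config.backoff_floor,
            backoff_step=config.backoff_step,
        )
        results = impute_cohort(val_matrix, tables, data.pedigree, strategy)
        results_to_frame(results).to_csv(out / "imputed.tsv", sep="\t", index=False)
        manifest.register(out / "imputed.tsv")

        stage = "score"
        report = score_concordance(results, split.withheld_ms, breeds)
        report.per_breed.to_csv(out / "concordance_by_breed.tsv", sep="\t", index=False)
        manifest.register(out / "concordance_by_breed.tsv")

        stage = "verify"
        imputed_ms = [
            g for g in (
                _imputed_to_ms(r) for r in results
            ) if g is not None
        ]
        reports, dist = verify_cohort(
            imputed_ms,
            data.pedigree,
            parent_genotypes=split.reference_ms,
            tolerance_bp=config.tolerance_bp,
            exclude_at=config.exclude_at,
        )
        reports_to_frame(reports).to_csv(out / "conflicts.tsv", sep="\t", index=False)
        manifest.register(out / "conflicts.tsv")
        (out / "conflict_summary.json").write_text(json.dumps(vars(dist), indent=1))
        manifest.register(out / "conflict_summary.json")
    except Exception as exc:  # noqa: BLE001 - re-raise with the stage name
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    manifest.verify()
    manifest.write(out / "manifest.json")
    return manifest


def _imputed_to_ms(result):
    from .types import MsGenotype

    if not result.complete:
        return None
    a, b = result.alleles
    return MsGenotype.make(result.animal_id, result.marker, a, b)
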