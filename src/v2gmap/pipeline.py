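"""Stage orchestration: wires the library modules into a reproducible
pipeline over a working directory of standard-format files.

Stages (see FORMATS.md for the file conventions):

* ``simulate``     — write a seeded synthetic study into the work dir
* ``digest``       — load/derive fragment maps and promoter windows
* ``atlas``        — consensus peaks -> reference OCR atlas with openness
* ``project``      — ibed calls -> OCR-pair promoter interactome
* ``map-variants`` — proxies -> variant-to-gene pairs and categories
* ``eqtl-test``    — empirical resampling test of v2g/eQTL overlap
* ``run-all``      — everything above in order

Each run writes a manifest (config hash, input checksums, seed, outputs) and
logs the counts surviving each filter step, mirroring the funnel a real-data
run would report.
"""

from __future__ import annotations

import dataclasses
import glob
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import atlas as atlas_mod
from . import enrichment, interactions, io as vio, variants
from .genome import FragmentMap, promoter_windows
from .simulate import SimulationConfig, simulate_study, write_study

logger = logging.getLogger("v2gmap")

STAGES = (
    "simulate",
    "digest",
    "atlas",
    "project",
    "map-variants",
    "eqtl-test",
    "run-all",
)


@dataclass
class PipelineParams:
    """All thresholds surfaced in one place, with the published defaults."""

    cell_types: tuple[str, ...] = ("naive", "tfh")
    focal_cell_type: str = "tfh"
    score_threshold: float = 5.0
    r2_threshold: float = 0.4
    promoter_upstream: int = 1500
    promoter_downstream: int = 500
    min_replicates: int = 2
    cpm_threshold: float = 1.5
    cpm_sample_fraction: float = 0.5
    pool_window_bp: int = 5_000_000
    empirical_reps: int = 100_000
    seed: int = 0
    include_promoter_resident_in_eqtl: bool = False
    nearest_gene_universe: str = "captured"  # 'captured' | 'all'

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineParams":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        if "cell_types" in data:
            data["cell_types"] = tuple(data["cell_types"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cell_types"] = list(d["cell_types"])
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class Pipeline:
    """Runs stages against a work directory; later stages reuse in-memory
    results of earlier ones and recompute dependencies when invoked alone."""

    def __init__(
        self,
        workdir: str | Path,
        outdir: str | Path | None = None,
        params: PipelineParams | None = None,
        sim_config: SimulationConfig | None = None,
    ) -> None:
        self.workdir = Path(workdir)
        self.outdir = Path(outdir) if outdir is not None else self.workdir / "results"
        self.params = params or PipelineParams()
        self.sim_config = sim_config
        self._fmap1 = None
        self._fmap4 = None
        self._windows = None
        self._transcripts = None
        self._atlas = None
        self._interactions = None
        self._v2g = None
        self._categories = None
        self._manifest: dict = {
            "stages": {},
            "params": self.params.to_dict(),
            "config_hash": hashlib.sha256(
                json.dumps(self.params.to_dict(), sort_keys=True).encode()
            ).hexdigest(),
        }

    # -- helpers ----------------------------------------------------------

    def _input(self, name: str) -> Path:
        path = self.workdir / name
        if not path.exists():
            raise FileNotFoundError(f"missing input file: {path}")
        return path

    def _record(self, stage: str, inputs: list[Path], outputs: list[Path]) -> None:
        self._manifest["stages"][stage] = {
            "inputs": {str(p): _sha256(p) for p in sorted(inputs)},
            "outputs": [str(p) for p in outputs],
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime()),
        }

    def write_manifest(self) -> Path:
        self.outdir.mkdir(parents=True, exist_ok=True)
        path = self.outdir / "manifest.json"
        vio.write_json(path, self._manifest)
        return path

    # -- stages -----------------------------------------------------------

    def run(self, stage: str) -> None:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
        self.outdir.mkdir(parents=True, exist_ok=True)
        if stage == "run-all":
            for s in ("digest", "atlas", "project", "map-variants", "eqtl-test"):
                self.run(s)
            return
        getattr(self, "stage_" + stage.replace("-", "_"))()

    def stage_simulate(self) -> None:
        config = self.sim_config or SimulationConfig(seed=self.params.seed)
        study = simulate_study(config)
        paths = write_study(study, self.workdir)
        logger.info(
            "simulate: %d transcripts, %d true OCRs, %d proxies",
            len(study.genome.transcripts),
            len(study.atac.ocrs),
            len(study.variants.proxies),
        )
        self._record("simulate", [], list(paths.values()))

    def stage_digest(self) -> None:
        rmap1 = self._input("digest_1frag.rmap")
        bait1 = self._input("digest_1frag.baitmap")
        tx_path = self._input("transcripts.tsv")
        self._fmap1 = vio.fragment_map_from_rmap(
            vio.read_rmap(rmap1), vio.read_baitmap(bait1), resolution=1
        )
        self._fmap4 = self._fmap1.concatenate(4)
        self._transcripts = vio.read_transcripts_tsv(tx_path)
        self._windows = promoter_windows(
            self._transcripts,
            self.params.promoter_upstream,
            self.params.promoter_downstream,
            {c: self._fmap1.chrom_length(c) for c in self._fmap1.chroms},
        )
        logger.info(
            "digest: %d fragments, %d transcripts, %d promoter windows",
            self._fmap1.n_fragments(),
            len(self._transcripts),
            len(self._windows),
        )
        self._record("digest", [rmap1, bait1, tx_path], [])

    def _require_digest(self) -> None:
        if self._fmap1 is None:
            self.stage_digest()

    def stage_atlas(self) -> None:
        self._require_digest()
        inputs: list[Path] = []
        merged = {}
        replicate_sets = {}
        for ct in self.params.cell_types:
            paths = sorted(glob.glob(str(self.workdir / f"peaks_{ct}_rep*.bed")))
            if not paths:
                raise FileNotFoundError(
                    f"missing input file: {self.workdir}/peaks_{ct}_rep*.bed"
                )
            inputs.extend(Path(p) for p in paths)
            reps = [vio.read_bed(p) for p in paths]
            replicate_sets[ct] = reps
            merged[ct] = atlas_mod.merge_replicate_peaks(
                reps, min_replicates=self.params.min_replicates
            )
            logger.info(
                "atlas: %s: %d replicate-supported merged peaks", ct, len(merged[ct])
            )
        blacklist_path = self.workdir / "blacklist.bed"
        blacklist = vio.read_bed(blacklist_path) if blacklist_path.exists() else []
        if blacklist_path.exists():
            inputs.append(blacklist_path)
        atl = atlas_mod.build_reference_ocrs(merged, blacklist)
        atlas_mod.call_openness(atl, replicate_sets)
        self._atlas = atl
        out_bed = self.outdir / "atlas.bed"
        atl.write_bed(out_bed)
        summary = {
            "n_reference_ocrs": len(atl),
            "n_open": {
                ct: sum(1 for o in atl.ocrs() if ct in o.open_in)
                for ct in self.params.cell_types
            },
        }
        counts_path = self.workdir / "ocr_counts.tsv"
        libs_path = self.workdir / "library_sizes.tsv"
        if counts_path.exists() and libs_path.exists():
            counts, libs = vio.read_count_matrix(counts_path, libs_path)
            retained = atlas_mod.cpm_filter(
                counts,
                libs,
                cpm_threshold=self.params.cpm_threshold,
                sample_fraction=self.params.cpm_sample_fraction,
            )
            summary["cpm_filter"] = {
                "n_input": int(counts.shape[0]),
                "n_retained": len(retained),
            }
            inputs.extend([counts_path, libs_path])
            logger.info(
                "atlas: CPM filter retained %d / %d regions",
                len(retained),
                counts.shape[0],
            )
        out_json = self.outdir / "atlas_summary.json"
        vio.write_json(out_json, summary)
        logger.info("atlas: %d reference OCRs", len(atl))
        self._record("atlas", inputs, [out_bed, out_json])

    def _require_atlas(self) -> None:
        if self._atlas is None:
            self.stage_atlas()

    def stage_project(self) -> None:
        self._require_atlas()
        inputs: list[Path] = []
        projected: dict[str, list[interactions.OcrInteraction]] = {}
        for ct in self.params.cell_types:
            calls = []
            for res in (1, 4):
                path = self.workdir / f"interactions_{ct}_{res}frag.ibed"
                if not path.exists():
                    continue
                inputs.append(path)
                calls.append(
                    interactions.read_ibed(
                        path, ct, res, score_threshold=self.params.score_threshold
                    )
                )
            if not calls:
                projected[ct] = []
                continue
            merged = interactions.merge_resolutions(
                calls[0], calls[1] if len(calls) > 1 else []
            )
            projected[ct] = interactions.project_to_ocr(
                merged, self._atlas, self._windows, ct
            )
            logger.info(
                "project: %s: %d significant calls -> %d OCR-pair interactions",
                ct,
                len(merged),
                len(projected[ct]),
            )
        self._interactions = projected
        frames = [
            interactions.interactions_to_frame(recs) for recs in projected.values()
        ]
        table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
        out_tsv = self.outdir / "ocr_interactions.tsv"
        table.to_csv(out_tsv, sep="\t", index=False)
        stats = {
            ct: interactions.connectivity_stats(recs, self._atlas, self._windows)
            for ct, recs in projected.items()
        }
        for ct in stats:  # per-gene map is bulky; keep the summary scalars
            stats[ct].pop("per_gene_partner_counts")
        out_json = self.outdir / "interaction_summary.json"
        vio.write_json(out_json, stats)
        self._record("project", inputs, [out_tsv, out_json])

    def _require_project(self) -> None:
        if self._interactions is None:
            self.stage_project()

    def stage_map_variants(self) -> None:
        self._require_project()
        proxies_path = self._input("proxies.tsv")
        proxies = vio.read_snp_table(proxies_path)
        ct = self.params.focal_cell_type
        kept = variants.filter_proxies(proxies, self.params.r2_threshold)
        accessible = variants.locate_in_ocr(kept, self._atlas, ct)
        prom = variants.promoter_resident_pairs(
            accessible, self._atlas, self._windows, ct
        )
        inter = variants.interaction_pairs(
            accessible, self._interactions[ct], self._atlas, self._windows, ct
        )
        universe = (
            self._captured_gene_ids()
            if self.params.nearest_gene_universe == "captured"
            else None
        )
        cats = variants.categorize_all(inter, proxies, self._transcripts, universe)
        logger.info(
            "map-variants: %d proxies in, %d pass r2>=%.2f, %d accessible, "
            "%d promoter-resident pairs, %d interaction pairs, %d categorized",
            len(proxies),
            len(kept),
            self.params.r2_threshold,
            len(accessible),
            len(prom),
            len(inter),
            len(cats),
        )
        pairs = pd.concat([prom, inter], ignore_index=True)
        pairs = pairs.merge(
            cats[["proxy_rsid", "category"]], on="proxy_rsid", how="left"
        )
        pairs["category"] = pairs["category"].fillna(".")
        out_pairs = self.outdir / "v2g_pairs.tsv"
        pairs.to_csv(out_pairs, sep="\t", index=False)
        out_cats = self.outdir / "categories.tsv"
        cats.to_csv(out_cats, sep="\t", index=False)
        summary = variants.summarize_categories(cats)
        summary["n_accessible"] = int(len(accessible))
        out_json = self.outdir / "category_summary.json"
        vio.write_json(out_json, summary)
        self._v2g = pairs
        self._categories = cats
        self._record(
            "map-variants", [proxies_path], [out_pairs, out_cats, out_json]
        )

    def _captured_gene_ids(self) -> set[str]:
        """Genes whose promoter window overlaps at least one bait fragment."""
        captured = set()
        for w in self._windows:
            chrom = w.interval.chrom
            if chrom not in self._fmap1.chroms:
                continue
            idx = self._fmap1.overlapping(chrom, w.interval.start, w.interval.end)
            flags = self._fmap1.bait_flags(chrom)
            if any(flags[i] for i in idx):
                captured.add(w.gene_id)
        return captured

    def stage_eqtl_test(self) -> None:
        if self._v2g is None:
            self.stage_map_variants()
        eqtl_path = self._input("eqtl_pairs.tsv")
        sent_path = self._input("sentinels.tsv")
        eqtl_df = vio.read_eqtl_pairs(eqtl_path)
        sentinels = pd.read_csv(sent_path, sep="\t", dtype={"chrom": str})
        sentinels["pos"] = sentinels["pos_1based"].astype(int) - 1
        routes = ["interaction"]
        if self.params.include_promoter_resident_in_eqtl:
            routes.append("promoter_resident")
        v2g = self._v2g[self._v2g["route"].isin(routes)]
        v2g_pairs = enrichment.make_pairs(
            zip(v2g["sentinel_rsid"], v2g["gene_symbol"])
        )
        eqtl_pairs = enrichment.make_pairs(
            zip(eqtl_df["sentinel_rsid"], eqtl_df["gene_symbol"])
        )
        pool = enrichment.build_null_pool(
            sentinels, self._transcripts, window_bp=self.params.pool_window_bp
        )
        result = enrichment.empirical_overlap_test(
            v2g_pairs,
            eqtl_pairs,
            pool,
            reps=self.params.empirical_reps,
            seed=self.params.seed,
        )
        logger.info(
            "eqtl-test: observed %d / null mean %.3f -> fold %s, p %.3g",
            result.observed,
            result.null_mean,
            f"{result.fold_enrichment:.2f}" if result.fold_enrichment else "NA",
            result.p_value,
        )
        out_json = self.outdir / "eqtl_test.json"
        vio.write_json(out_json, result.to_dict())
        out_hist = self.outdir / "eqtl_null_histogram.tsv"
        with open(out_hist, "w") as fh:
            fh.write("overlap\tcount\n")
            for k, v in sorted(result.null_histogram.items()):
                fh.write(f"{k}\t{v}\n")
        self._record("eqtl-test", [eqtl_path, sent_path], [out_json, out_hist])


def run_pipeline(
    workdir: str | Path,
    stage: str,
    outdir: str | Path | None = None,
    params: PipelineParams | None = None,
    sim_config: SimulationConfig | None = None,
) -> Pipeline:
    pipe = Pipeline(workdir, outdir=outdir, params=params, sim_config=sim_config)
    if stage == "run-all" and sim_config is not None:
        pipe.run("simulate")
    pipe.run(stage)
    pipe.write_manifest()
    return pipe
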