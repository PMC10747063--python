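"""End-to-end orchestration: config -> full report set + run manifest.

Stage order mirrors the analysis: read/merge -> relative abundance ->
variant proportions -> site marginalization / variant combination ->
acetylation degrees -> log-ratio group statistics -> hierarchical
clustering.  Every run writes a JSON manifest recording versions, the seed,
a hash of the resolved configuration, the runtime decisions taken (merge
semantics, dropped features, zero-replacement deltas are logged), and a
checksum per output file; identical config + seed give identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .io import merge_groups, read_peak_area_table, write_peak_area_table
from .quantify import (
    acetyl_degrees,
    combined_site_marks,
    compositions,
    site_marks,
    variant_proportions,
)
from .regions import ValidationError, VARIANT_REGIONS
from .simulate import NoiseModel, design_truth, generate_dataset, paper_like_preset
from .stats import build_profile_matrix, compare_groups, hclust_average

logger = logging.getLogger("histoptm")


@dataclass
class RunConfig:
    """Everything a reproduction run needs.

    Either ``input_path`` (a peak-area table) or ``preset=True`` (generate
    the synthetic study-design dataset with ``seed``) must be set.
    Comparisons are explicit ordered group pairs — no all-vs-all default.
    """

    output_dir: str
    input_path: str | None = None
    preset: bool = False
    seed: int = 0
    sigma: float = 0.25
    merges: list[dict] = field(default_factory=list)  # {sources: [...], target: str}
    comparisons: list[tuple[str, str]] = field(default_factory=list)
    cluster_scopes: list[str] = field(default_factory=lambda: ["all-peptides"])
    cluster_unit: str = "group-mean"
    ttest_flavor: str = "student"
    delta_factor: float = 0.65
    combine_weighting: str = "median"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        raw["comparisons"] = [tuple(pair) for pair in raw.get("comparisons", [])]
        return cls(**raw)

    def resolved(self) -> dict:
        d = asdict(self)
        d["comparisons"] = [list(p) for p in self.comparisons]
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the run manifest (also written to disk)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    decisions: list[str] = []

    # -- stage: data -------------------------------------------------------
    stage = "data"
    try:
        if config.preset:
            designs = paper_like_preset()
            noise = NoiseModel(sigma=config.sigma, seed=config.seed)
            records = generate_dataset(designs, noise)
            (out / "ground_truth.json").write_text(
                json.dumps(design_truth(designs, noise), indent=1, sort_keys=True),
                encoding="utf-8",
            )
            decisions.append(
                f"synthetic preset dataset (sigma={config.sigma}, seed={config.seed})"
            )
        elif config.input_path:
            records = read_peak_area_table(config.input_path)
        else:
            raise ValidationError("config needs input_path or preset: true")

        # -- stage: merge --------------------------------------------------
        stage = "merge"
        for directive in config.merges:
            records = merge_groups(
                records, directive["sources"], directive["target"]
            )
            decisions.append(
                f"merged {directive['sources']} -> {directive['target']} "
                "(areas summed per replicate/region/form)"
            )
        write_peak_area_table(records, out / "records.tsv")

        # -- stage: quantification ----------------------------------------
        stage = "relative_abundance"
        comps = compositions(records)
        comps.to_csv(out / "compositions.tsv", sep="\t", index=False)

        stage = "variant_proportion"
        vps = variant_proportions(records)
        vp_rows = []
        for group, vp in vps.items():
            for rep, p in sorted(vp.per_replicate.items()):
                vp_rows.append((group, rep, p, vp.p_h31, vp.ratio_text))
        pd.DataFrame(
            vp_rows,
            columns=["sample_group", "replicate", "p_h31_replicate",
                     "p_h31_median", "ratio_text"],
        ).to_csv(out / "variant_proportions.tsv", sep="\t", index=False)

        stage = "site_marks"
        marks = site_marks(comps)
        combined = combined_site_marks(marks, vps, config.combine_weighting)
        decisions.append(
            f"combined K27/K36 marks weighted by group-{config.combine_weighting} "
            "variant proportion"
        )
        all_marks = pd.concat([marks, combined], ignore_index=True)
        all_marks.to_csv(out / "site_marks.tsv", sep="\t", index=False)

        stage = "acetyl_degree"
        degrees = acetyl_degrees(comps)
        degrees.to_csv(out / "acetyl_degrees.tsv", sep="\t", index=False)

        # -- stage: statistics --------------------------------------------
        stage = "stats"
        reports = []
        for group_a, group_b in config.comparisons:
            present = set(records["sample_group"])
            for g in (group_a, group_b):
                if g not in present:
                    raise ValidationError(f"comparison group {g!r} not in data")
            reports.append(
                compare_groups(
                    comps, group_a, group_b,
                    flavor=config.ttest_flavor,
                    delta_factor=config.delta_factor,
                )
            )
        if reports:
            pd.concat(reports, ignore_index=True).to_csv(
                out / "stats_report.tsv", sep="\t", index=False
            )

        # -- stage: clustering --------------------------------------------
        stage = "clustering"
        for scope in config.cluster_scopes:
            matrix, dropped = build_profile_matrix(
                comps, scope=scope, unit=config.cluster_unit,
                delta_factor=config.delta_factor,
            )
            matrices = matrix if isinstance(matrix, dict) else {"all-peptides": matrix}
            for name, M in matrices.items():
                result = hclust_average(M)
                tag = name.replace("/", "_")
                link = pd.DataFrame(
                    result.linkage,
                    columns=["child_a", "child_b", "height", "count"],
                )
                link.to_csv(out / f"linkage_{tag}.tsv", sep="\t", index=False)
                (out / f"dendrogram_{tag}.nwk").write_text(
                    result.newick() + "\n", encoding="utf-8"
                )
            for region_id, feats in dropped.items():
                if feats:
                    decisions.append(
                        f"clustering[{scope}]: dropped {len(feats)} feature(s) of "
                        f"{region_id} missing in some unit"
                    )
    except ValidationError as err:
        raise ValidationError(f"stage {stage!r} failed: {err}") from err

    # -- manifest ----------------------------------------------------------
    n_region_ids = records["region_id"].nunique()
    n_peptides = n_region_ids - (
        1 if all(r in set(records["region_id"]) for r in VARIANT_REGIONS) else 0
    )
    # hash the analytic configuration only — where outputs land is irrelevant
    config_json = json.dumps(
        {k: v for k, v in config.resolved().items() if k != "output_dir"},
        sort_keys=True,
    )
    outputs = sorted(
        p.name for p in out.iterdir() if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "package": "histoptm",
        "version": __version__,
        "seed": config.seed,
        "config": config.resolved(),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "groups": sorted(set(records["sample_group"])),
        "n_groups": int(records["sample_group"].nunique()),
        "n_region_ids": int(n_region_ids),
        "n_peptides": int(n_peptides),
        "decisions": decisions,
        "outputs": {name: _sha256(out / name) for name in outputs},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True), encoding="utf-8"
    )
    return manifest
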