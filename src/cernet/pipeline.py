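"""End-to-end orchestration of the ceRNA reconstruction pipeline.

Stage order: differential screening -> target prediction on the
differentially expressed features -> coexpression filters -> triplet
assembly per stratum -> network build, hub extraction -> enrichment of
network mRNAs.  Every stage artifact is written as TSV/SIF/GraphML and
the run closes with a JSON summary that echoes the full effective
parameter set, so a run is reproducible from its summary plus inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

import cernet
from cernet import coexpression as cx
from cernet import diffexpr as de
from cernet import enrichment as en
from cernet import network as nw
from cernet import targets as tg
from cernet.core_io import read_expression, read_gmt, write_network
from cernet.errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and the full effective threshold set of one pipeline run."""

    input_dir: str = "."
    output_dir: str = "results"
    fc_threshold: float = 2.0
    de_p: float = 0.05
    score_min: float = 160.0
    energy_max: float = -30.0
    r_min: float = 0.90
    coexpr_p: float = 0.001
    anticorr_p: float = 0.05
    require_lnc_anticorr: bool = True
    hub_degree: int = 8
    hub_stage: str = "post"  # "post" (default) or "during"
    enrich_p: float = 0.05
    top_n: int = 30
    ease: bool = False
    seed: int = 0
    log_level: str = "INFO"
    scheme_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("de_p", "coexpr_p", "anticorr_p", "enrich_p"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"{name}={v} must lie in (0, 1)")
        if not 0.0 < self.r_min < 1.0:
            raise ValidationError(f"r_min={self.r_min} must lie in (0, 1)")
        if self.fc_threshold <= 0:
            raise ValidationError("fc_threshold must be positive")
        if self.hub_degree < 0:
            raise ValidationError("hub_degree must be non-negative")
        if self.hub_stage not in ("post", "during"):
            raise ValidationError("hub_stage must be 'post' or 'during'")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def scheme(self) -> tg.ScoringScheme:
        return tg.ScoringScheme(score_min=self.score_min, energy_max_kcal=self.energy_max,
                                **self.scheme_overrides)


def _input_paths(input_dir: Path) -> dict[str, Path]:
    return {
        "lncrna": input_dir / "lncrna_expression.tsv",
        "mirna": input_dir / "mirna_expression.tsv",
        "mrna": input_dir / "mrna_expression.tsv",
        "sheet": input_dir / "samples.tsv",
        "mirna_fasta": input_dir / "mirna.fasta",
        "target_fasta": input_dir / "targets.fasta",
        "gmt": input_dir / "genesets.gmt",
    }


def _annotate_pairs_unfiltered(bundle, pairs):
    """Annotate pairs with (r, p) without requiring anticorrelation."""
    out = []
    for pair in pairs:
        mat = bundle.lncrna if pair.target_class == "lncRNA" else bundle.mrna
        x = bundle.mirna.loc[pair.mirna_id].to_numpy(dtype=float)
        y = mat.loc[pair.target_id].to_numpy(dtype=float)
        r, p = cx.pearson_with_p(x, y)
        out.append((pair, cx.CoexpressionEdge(pair.mirna_id, "miRNA", pair.target_id,
                                              pair.target_class, r, p, x.size)))
    return out


def _edge_table(annotated) -> pd.DataFrame:
    return pd.DataFrame(
        [dict(a_id=e.a_id, a_class=e.a_class, b_id=e.b_id, b_class=e.b_class,
              r=e.r, p=e.p_value, n=e.n_samples)
         for e in annotated],
        columns=["a_id", "a_class", "b_id", "b_class", "r", "p", "n"])


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full reconstruction and return the JSON-able summary."""
    in_dir = Path(config.input_dir)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = _input_paths(in_dir)
    for key in ("lncrna", "mirna", "mrna", "sheet", "mirna_fasta", "target_fasta"):
        if not paths[key].exists():
            raise ValidationError(f"missing input file: {paths[key]}")

    bundle = read_expression(paths["lncrna"], paths["mirna"], paths["mrna"], paths["sheet"])

    # 1. differential screening
    records = {cls: de.two_class_de(bundle, cls, config.fc_threshold, config.de_p)
               for cls in ("lncRNA", "miRNA", "mRNA")}
    strata = {cls: de.stratify(recs, config.fc_threshold, config.de_p)
              for cls, recs in records.items()}
    for cls, recs in records.items():
        de.de_table(recs).to_csv(out_dir / f"de_{cls}.tsv", sep="\t", index=False)

    # 2. target prediction restricted to differentially expressed features
    scheme = config.scheme()
    mirna_seqs = tg.read_fasta(paths["mirna_fasta"])
    target_seqs = tg.read_fasta(paths["target_fasta"])
    de_mirnas = strata["miRNA"]["up"] | strata["miRNA"]["down"]
    de_lncs = strata["lncRNA"]["up"] | strata["lncRNA"]["down"]
    de_mrnas = strata["mRNA"]["up"] | strata["mRNA"]["down"]
    mir_sub = {k: v for k, v in mirna_seqs.items() if k in de_mirnas}
    lnc_sub = {k: v for k, v in target_seqs.items() if k in de_lncs}
    mrna_sub = {k: v for k, v in target_seqs.items() if k in de_mrnas}
    lnc_pairs = tg.predict_targets(mir_sub, lnc_sub, scheme, target_class="lncRNA")
    mrna_pairs = tg.predict_targets(mir_sub, mrna_sub, scheme, target_class="mRNA")

    # 3. coexpression filters
    if config.require_lnc_anticorr:
        lnc_annotated = cx.mirna_anticorrelation_filter(bundle, lnc_pairs, config.anticorr_p)
    else:
        lnc_annotated = _annotate_pairs_unfiltered(bundle, lnc_pairs)
    mrna_annotated = cx.mirna_anticorrelation_filter(bundle, mrna_pairs, config.anticorr_p)
    _edge_table([e for _, e in lnc_annotated]).to_csv(
        out_dir / "mirna_lncrna_edges.tsv", sep="\t", index=False)
    _edge_table([e for _, e in mrna_annotated]).to_csv(
        out_dir / "mirna_mrna_edges.tsv", sep="\t", index=False)

    summary: dict = {
        "package_version": cernet.__version__,
        "parameters": {**asdict(config), "scheme": asdict(scheme)},
        "seed": config.seed,
        "de_counts": {cls: {"up": len(s["up"]), "down": len(s["down"])}
                      for cls, s in strata.items()},
        "n_target_pairs": {"lncRNA": len(lnc_pairs), "mRNA": len(mrna_pairs)},
        "strata": {},
    }

    # 4-5. per-stratum coexpression edges, triplets, networks, hubs
    for stratum in nw.STRATA:
        signs = nw.STRATUM_SIGNS[stratum]
        lnc_ids = strata["lncRNA"][signs["lncRNA"]]
        mrna_ids = strata["mRNA"][signs["mRNA"]]
        edges = cx.lncrna_mrna_edges(bundle, lnc_ids, mrna_ids,
                                     r_min=config.r_min, p_max=config.coexpr_p)
        _edge_table(edges).to_csv(out_dir / f"lncrna_mrna_edges_{stratum}.tsv",
                                  sep="\t", index=False)
        triplets = nw.assemble_triplets(strata, lnc_annotated, mrna_annotated, edges, stratum)
        nw.triplet_table(triplets).to_csv(out_dir / f"triplets_{stratum}.tsv",
                                          sep="\t", index=False)
        network = nw.build_network(triplets, stratum=stratum)
        hub = nw.extract_hub_subnetwork(network, config.hub_degree)
        primary = hub if config.hub_stage == "during" else network
        for fmt, ext in (("sif", "sif"), ("graphml", "graphml"), ("tsv", "edges.tsv")):
            write_network(network, out_dir / f"network_{stratum}.{ext}", fmt)
            write_network(hub, out_dir / f"hub_{stratum}.{ext}", fmt)

        # 6. enrichment of the stratum network's mRNAs
        enrichment_summary = {}
        if paths["gmt"].exists():
            collection = read_gmt(paths["gmt"], namespace="GO-BP")
            universe = set(bundle.mrna.index)
            selected = primary.nodes_of_class("mRNA")
            enr = en.enrich(selected, collection, universe, ease=config.ease)
            table, counts = en.report_top(enr, config.enrich_p, config.top_n)
            table.to_csv(out_dir / f"enrichment_{stratum}.tsv", sep="\t", index=False)
            enrichment_summary = {
                "significant_per_namespace": counts,
                "top_terms": table["term_id"].head(5).tolist(),
            }

        hub_lncs = sorted(hub.nodes_of_class("lncRNA"))
        summary["strata"][stratum] = {
            "n_coexpression_edges": len(edges),
            "n_triplets": len(triplets),
            "network": network.summary(),
            "hub_lncRNAs": hub_lncs,
            "hub_network": hub.summary(),
            "enrichment": enrichment_summary,
        }

    summary_path = out_dir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    logger.info("pipeline complete; summary at %s", summary_path)
    return summary
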