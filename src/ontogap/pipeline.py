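"""Pipeline stages tying the modules together, plus their configuration.

Each ``run_*`` function is deterministic given (config, seed) and returns a
JSON-serializable report; the CLI is a thin wrapper over these.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import io as _io
from .candidates import generate_candidates
from .derived import DEFAULT_CEILING, DEFAULT_CHAIN_DEPTH
from .missing import ProposalLog, proposal_to_jsonl, propose
from .naming import TemplateNamer, build_instances, evaluate_namer, instances_tsv, split_dataset
from .nonlattice import enumerate_subgraphs
from .ontology import Ontology
from .synthetic import make_vulva_fixture, make_thyroid_fixture
from .validation import (
    build_np_index,
    load_jsonl_corpus,
    load_lexicon_tsv,
    load_mrconso,
    normalize_lexicon,
    validate_proposal,
)

log = logging.getLogger("ontogap")


@dataclass
class Config:
    """Every threshold of the method is a named key with its standard default."""

    ontology: str = ""            # path to fixture dir or RF2 snapshot dir
    ontology_format: str = "fixture"  # fixture | rf2
    max_subgraph_size: int = 10
    size_inclusive: bool = True
    min_level: int = 10
    chain_depth: int = DEFAULT_CHAIN_DEPTH
    generality_ceiling: int = DEFAULT_CEILING
    split_ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0
    lexicon: str = ""             # MRCONSO (.rrf) or TSV path
    corpus: str = ""              # JSON-lines corpus path
    newer_ontology: str = ""      # fixture dir of a newer release
    out_dir: str = "ontogap_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "split_ratios" in data:
            data["split_ratios"] = tuple(data["split_ratios"])
        return cls(**data)


def load_ontology(cfg: Config) -> Ontology:
    if not cfg.ontology:
        raise ValueError("config field 'ontology' is required")
    if cfg.ontology_format == "rf2":
        return _io.load_rf2(cfg.ontology)
    if cfg.ontology_format == "fixture":
        return _io.load_fixture(cfg.ontology)
    raise ValueError(f"config field 'ontology_format' must be fixture or rf2, got {cfg.ontology_format!r}")


def _write(out_dir: Path, name: str, text: str) -> Path:
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / name
    path.write_text(text, encoding="utf-8")
    return path


def run_audit(cfg: Config, o: Ontology | None = None) -> dict:
    """Detect non-lattice subgraphs and report them."""
    o = o or load_ontology(cfg)
    sgs = enumerate_subgraphs(o, cfg.max_subgraph_size, cfg.size_inclusive)
    log.info("audit: %d non-lattice subgraphs (size <= %d)", len(sgs), cfg.max_subgraph_size)
    report = {
        "n_subgraphs": len(sgs),
        "subgraphs": [json.loads(sg.to_json(o)) for sg in sgs],
    }
    _write(Path(cfg.out_dir), "audit.json", json.dumps(report, sort_keys=True, indent=1))
    return report


def run_propose(cfg: Config, o: Ontology | None = None) -> dict:
    """Full proposal pipeline: subgraphs → candidates → intersections."""
    o = o or load_ontology(cfg)
    sgs = enumerate_subgraphs(o, cfg.max_subgraph_size, cfg.size_inclusive)
    cands = generate_candidates(o, sgs, cfg.min_level)
    plog = ProposalLog()
    proposals = propose(o, cands, cfg.chain_depth, cfg.generality_ceiling, plog)
    namer = TemplateNamer()
    from .naming import serialize_definition

    proposals = [p.with_fsn(namer(serialize_definition(o, p.definition))) for p in proposals]
    log.info(
        "propose: %d subgraphs, %d candidates, %d proposals "
        "(%d empty, %d suppressed as existing, %d merged)",
        len(sgs), plog.candidates, plog.proposals,
        plog.empty_intersections, plog.suppressed_existing, plog.merged_duplicates,
    )
    _write(
        Path(cfg.out_dir),
        "proposals.jsonl",
        "".join(proposal_to_jsonl(p) + "\n" for p in proposals),
    )
    report = {"counts": asdict_counts(plog, len(sgs)), "proposals_file": "proposals.jsonl"}
    _write(Path(cfg.out_dir), "propose.json", json.dumps(report, sort_keys=True, indent=1))
    return report | {"proposals": proposals, "ontology": o}


def asdict_counts(plog: ProposalLog, n_subgraphs: int) -> dict:
    return {"subgraphs": n_subgraphs, **asdict(plog)}


def run_name_data(cfg: Config, o: Ontology | None = None) -> dict:
    """Serialize every defined concept and emit 80/10/10 split datasets."""
    o = o or load_ontology(cfg)
    instances = build_instances(o)
    by_id = {i.concept: i for i in instances}
    train, valid, test = split_dataset([i.concept for i in instances], cfg.split_ratios, cfg.seed)
    out = Path(cfg.out_dir)
    for name, ids in (("train", train), ("valid", valid), ("test", test)):
        _write(out, f"{name}.tsv", instances_tsv([by_id[c] for c in ids]))
        _write(out, f"{name}.ids", "\n".join(ids) + "\n")
    evaluation = evaluate_namer(TemplateNamer(), [by_id[c] for c in test])
    metrics = {
        "rouge1": round(100 * evaluation.rouge.rouge1, 2),
        "rouge2": round(100 * evaluation.rouge.rouge2, 2),
        "rougeL": round(100 * evaluation.rouge.rougeL, 2),
        "exact": evaluation.exact,
        "n_test": evaluation.n,
    }
    report = {
        "n_instances": len(instances),
        "sizes": {"train": len(train), "valid": len(valid), "test": len(test)},
        "baseline_metrics": metrics,
    }
    _write(out, "name_data.json", json.dumps(report, sort_keys=True, indent=1))
    log.info("name-data: %d instances split %s", len(instances), report["sizes"])
    return report


def run_validate(cfg: Config, o: Ontology | None = None, proposals=None) -> dict:
    """Validate proposals against lexicon, corpus and a newer release."""
    if proposals is None:
        result = run_propose(cfg, o)
        proposals, o = result["proposals"], result["ontology"]
    lexicon = None
    if cfg.lexicon:
        raw = (
            load_mrconso(cfg.lexicon)
            if cfg.lexicon.endswith((".rrf", ".RRF"))
            else load_lexicon_tsv(cfg.lexicon)
        )
        lexicon = normalize_lexicon(raw, o)
    elif cfg.lexicon == "" :
        log.warning("validate: no lexicon configured; lexicon stage skipped")
    index = None
    if cfg.corpus:
        index = build_np_index(load_jsonl_corpus(cfg.corpus), o=o)
    else:
        log.warning("validate: no corpus configured; corpus stage skipped")
    newer = None
    if cfg.newer_ontology:
        newer = _io.load_fixture(cfg.newer_ontology)
    else:
        log.warning("validate: no newer release configured; release stage skipped")
    rows = []
    n_validated = 0
    for p in proposals:
        res = validate_proposal(p, o, lexicon, index, newer)
        n_validated += res.validated
        rows.append(
            {
                "predicted_fsn": p.predicted_fsn,
                "by_lexicon": res.by_lexicon,
                "by_corpus": res.by_corpus,
                "by_release": list(res.by_release) if res.by_release else None,
                "validated": res.validated,
            }
        )
    report = {"n_proposals": len(proposals), "n_validated": n_validated, "results": rows}
    _write(Path(cfg.out_dir), "validation.json", json.dumps(report, sort_keys=True, indent=1))
    log.info("validate: %d/%d proposals validated", n_validated, len(proposals))
    return report


def run_fixtures(out_dir: str | Path) -> dict:
    """Write the packaged worked-example fixtures in the fixture dialect."""
    out = Path(out_dir)
    _io.write_fixture(make_vulva_fixture(), out / "vulva")
    _io.write_fixture(make_thyroid_fixture(), out / "thyroid")
    return {"written": [str(out / "vulva"), str(out / "thyroid")]}
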