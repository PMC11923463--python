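"""End-to-end orchestration: preprocess -> extract -> sentiment -> trends ->
topics -> network, from a single config with one seed.

The run report carries every count needed to audit attrition (read, URL-
removed, mentions, retained entities, scored, edges) and contains nothing
non-deterministic, so two runs with the same config and seed produce
byte-identical reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Optional, Sequence

import yaml

from . import corpus_io, entities, lda, network, sentiment
from .corpus_io import StudyWindow

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline halted at stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    corpus_path: str
    lexicon_path: str
    out_dir: str
    corpus_format: str = "jsonl"
    atc_path: Optional[str] = None
    allowlist_path: Optional[str] = None
    window: StudyWindow = field(default_factory=StudyWindow)
    min_drug: int = entities.DEFAULT_MIN_DRUG_MENTIONS
    min_symptom: int = entities.DEFAULT_MIN_SYMPTOM_MENTIONS
    tau_drug_drug: float = network.DEFAULT_TAU_DRUG_DRUG
    tau_drug_symptom: float = network.DEFAULT_TAU_DRUG_SYMPTOM
    lda_k: Optional[int] = None
    lda_k_grid: Sequence[int] = (5, 10, 15, 20)
    lda_alpha: Optional[float] = None
    lda_beta: float = 0.01
    lda_iters: int = 200
    top_k: int = 5
    scorer: str = "baseline"
    seed: int = 0

    def validate(self) -> None:
        for name in ("min_drug", "min_symptom"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("tau_drug_drug", "tau_drug_symptom"):
            tau = getattr(self, name)
            if not 0.0 <= tau < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        for path in (self.corpus_path, self.lexicon_path, self.atc_path):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(path)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        window = raw.pop("window", None)
        cfg = cls(**raw)
        if window:
            cfg.window = StudyWindow(
                start_date=date.fromisoformat(str(window["start"])),
                end_date=date.fromisoformat(str(window["end"])),
            )
        return cfg


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineStageError(name, exc) from exc

        return wrapper

    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order; returns the run report (also written to
    ``<out_dir>/report.json``). Partial outputs are preserved on failure."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "seed": config.seed,
        "window": [config.window.start_date.isoformat(), config.window.end_date.isoformat()],
        "stages": {},
        "outputs": {},
    }

    # --- preprocess -------------------------------------------------------
    @_stage("preprocess")
    def preprocess():
        result = corpus_io.read_corpus(
            config.corpus_path, fmt=config.corpus_format, window=config.window
        )
        kept, n_removed = corpus_io.filter_urls(result.records)
        allow = None
        if config.allowlist_path:
            allow = [
                line.strip()
                for line in Path(config.allowlist_path).read_text(encoding="utf-8").splitlines()
                if line.strip()
            ]
        kept = [
            corpus_io.TweetRecord(
                r.tweet_id, r.user_id, r.timestamp, corpus_io.mask_users(r.text, allow)
            )
            for r in kept
        ]
        report["stages"]["preprocess"] = {
            "read": len(result.records),
            "skipped_malformed": result.n_skipped,
            "url_removed": n_removed,
            "kept": len(kept),
        }
        path = out / "kept.jsonl"
        corpus_io.write_corpus(kept, path)
        report["outputs"]["kept"] = str(path)
        return kept

    kept = preprocess()
    if not kept:
        report["halted_at"] = "preprocess"
        _write_report(report, out)
        return report

    # --- extract ----------------------------------------------------------
    @_stage("extract")
    def extract():
        lexicon = entities.load_lexicon(config.lexicon_path)
        matcher = entities.build_matcher(lexicon)
        mentions = entities.extract_corpus(kept, matcher)
        counts = entities.mention_counts(mentions)
        retained = entities.frequency_filter(
            counts, matcher.class_of, config.min_drug, config.min_symptom
        )
        kept_mentions = [m for m in mentions if m.canonical in retained]
        report["stages"]["extract"] = {
            "mentions": len(mentions),
            "distinct_canonicals": len(counts),
            "retained_entities": len(retained),
            "retained_mentions": len(kept_mentions),
        }
        path = out / "mentions.jsonl"
        entities.write_mentions(kept_mentions, path)
        report["outputs"]["mentions"] = str(path)
        return matcher, kept_mentions, retained

    matcher, mentions, retained = extract()

    # --- sentiment --------------------------------------------------------
    @_stage("sentiment")
    def score():
        scored = sentiment.score_mentions(kept, mentions, scorer_id=config.scorer)
        report["stages"]["sentiment"] = {
            "scored": len(scored),
            "distributions": {
                c: [round(p, 6) for p in probs]
                for c, probs in sorted(sentiment.sentiment_distribution(scored).items())
            },
        }
        path = out / "scored.jsonl"
        sentiment.write_scored(scored, path)
        report["outputs"]["scored"] = str(path)
        return scored

    scored = score()

    # --- trends -----------------------------------------------------------
    @_stage("trends")
    def trends():
        counts = entities.mention_counts(mentions)
        top = sentiment.top_k_concepts(
            counts, k=config.top_k, concept_class="drug", class_of=matcher.class_of
        )
        timestamps = {r.tweet_id: r.timestamp for r in kept}
        series_paths = {}
        for canonical in top:
            series = sentiment.mention_series(mentions, timestamps, canonical, config.window)
            path = out / f"trend_{canonical.replace(' ', '_')}.csv"
            sentiment.write_series(series, path)
            series_paths[canonical] = str(path)
        report["stages"]["trends"] = {
            "top_drugs": top,
            "totals": {c: counts[c] for c in top},
        }
        report["outputs"]["trends"] = series_paths
        return top

    trends()

    # --- topics -----------------------------------------------------------
    @_stage("topics")
    def topics():
        drug_tweet_ids = {m.tweet_id for m in mentions if m.concept_class == "drug"}
        texts = [r.text for r in kept if r.tweet_id in drug_tweet_ids]
        if not texts:
            report["stages"]["topics"] = {"documents": 0, "skipped": True}
            return
        corpus = lda.preprocess_for_lda(texts, bigram_min_count=max(2, len(texts) // 100))
        if config.lda_k is not None:
            k_star, table = config.lda_k, []
        else:
            k_star, table = lda.select_k(
                corpus,
                config.lda_k_grid,
                alpha=config.lda_alpha,
                beta=config.lda_beta,
                n_iters=config.lda_iters,
                seeds=(config.seed,),
            )
        state = lda.fit_lda_gibbs(
            corpus,
            K=k_star,
            alpha=config.lda_alpha,
            beta=config.lda_beta,
            n_iters=config.lda_iters,
            seed=config.seed,
        )
        summaries = lda.topic_summaries(state, corpus, topn=20)
        path = out / "topics.csv"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("topic,rank,token,probability\n")
            for s in summaries:
                for rank, (token, prob) in enumerate(s.keywords, 1):
                    fh.write(f"{s.topic},{rank},{token},{prob:.6g}\n")
        report["stages"]["topics"] = {
            "documents": corpus.n_docs,
            "vocabulary": corpus.n_words,
            "k": k_star,
            "selection_table": [
                {k: round(v, 6) if isinstance(v, float) else v for k, v in row.items()}
                for row in table
            ],
        }
        report["outputs"]["topics"] = str(path)

    topics()

    # --- network ----------------------------------------------------------
    @_stage("network")
    def networks():
        tweet_ids = [r.tweet_id for r in kept]
        drugs = {c for c in retained if matcher.class_of.get(c) == "drug"}
        symptoms = {c for c in retained if matcher.class_of.get(c) == "symptom"}
        info = {}
        atc_map = matcher.atc_map()
        if config.atc_path:
            for entry in entities.load_lexicon(config.atc_path):
                if entry.atc_code:
                    atc_map[entry.canonical] = entry.atc_code
        if drugs:
            inc = network.build_incidence(mentions, drugs, tweet_ids)
            G = network.build_network(inc, tau=config.tau_drug_drug)
            if G.number_of_nodes():
                part = network.louvain(G, seed=config.seed)
                network.annotate_atc(G, atc_map)
                path = out / "drug_drug.gexf"
                network.export_network(G, path, fmt="gexf", partition=part)
                network.export_network(
                    G, out / "drug_drug_edges.csv", fmt="edge-csv", partition=part
                )
                info["drug_drug"] = {
                    "nodes": G.number_of_nodes(),
                    "edges": G.number_of_edges(),
                    "communities": len(set(part.membership.values())),
                    "modularity": round(part.q, 9),
                }
                report["outputs"]["drug_drug"] = str(path)
        if drugs and symptoms:
            drug_inc = network.build_incidence(mentions, drugs, tweet_ids)
            sym_inc = network.build_incidence(mentions, symptoms, tweet_ids)
            G = network.drug_symptom_network(drug_inc, sym_inc, tau=config.tau_drug_symptom)
            path = out / "drug_symptom.gexf"
            network.export_network(G, path, fmt="gexf")
            info["drug_symptom"] = {
                "nodes": G.number_of_nodes(),
                "edges": G.number_of_edges(),
            }
            report["outputs"]["drug_symptom"] = str(path)
        report["stages"]["network"] = info

    networks()

    _write_report(report, out)
    return report


def _write_report(report: dict, out: Path) -> None:
    path = out / "report.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    report["outputs"]["report"] = str(path)
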