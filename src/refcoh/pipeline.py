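"""End-to-end orchestration: simulate -> annotate -> dynamics ->
semantics -> fit -> report.

Every stage reads and writes plain files (JSONL corpus, TSV span
annotations, CSV result tables), so each is independently re-runnable,
and a run manifest records the config hash and a checksum per output so
deterministic stages can be verified to reproduce bit-identically.
All randomness flows from named seeds in the run configuration; no
module-level state is shared between runs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotation import (
    AnnotationSet,
    ManualFlags,
    NPCategory,
    NPSpan,
    aggregate_definiteness,
    annotate_transcript,
    count_categories,
    MACRO_TYPES,
)
from .datamodel import (
    TranscriptSet,
    read_transcripts,
    write_table,
    write_transcripts,
)
from .dynamics import exponentiality_test, group_gap_samples
from .inference import build_design, gee_gaussian_exchangeable, poisson_glm_offset
from .semantics import (
    consecutive_cosine_similarity,
    image_text_similarity,
    preprocess_for_similarity,
    pseudo_perplexity,
    stub_provider,
)
from .simulate import GeneratorConfig, simulate_corpus

ALL_STAGES = ("simulate", "annotate", "dynamics", "semantics", "fit", "report")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass(slots=True)
class RunConfig:
    out_dir: Path
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    corpus_path: Path | None = None  # external corpus instead of simulation
    spans_path: Path | None = None
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    alpha: float = 0.05
    n_sim: int = 2000
    min_gaps: int = 8
    arrival_method: str = "lilliefors_mc"
    jitter: bool = True  # de-grid integer token gaps before KS testing
    provider_dim: int = 64

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(cfg: RunConfig) -> str:
    payload = {k: str(v) for k, v in asdict(cfg).items()}
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def spans_to_frame(annotations: list[AnnotationSet]) -> pd.DataFrame:
    rows = []
    for a in annotations:
        for s in a.spans:
            rows.append(
                {
                    "participant_id": a.participant_id,
                    "group": a.group,
                    "picture_id": a.picture_id,
                    "start": s.span.start,
                    "end": s.span.end,
                    "head": s.span.head_index,
                    "category": s.category.value,
                    "anomaly": int(s.span.manual_flags.anomaly),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "group",
            "picture_id",
            "start",
            "end",
            "head",
            "category",
            "anomaly",
        ],
    )


def counts_frame(annotations: list[AnnotationSet]) -> pd.DataFrame:
    """One row per narration: category counts, anomalies, word count."""
    rows = []
    for a in annotations:
        row = {
            "participant_id": a.participant_id,
            "group": a.group,
            "picture_id": a.picture_id,
        }
        row.update(count_categories(a))
        row.update(aggregate_definiteness(row))
        rows.append(row)
    return pd.DataFrame(rows)


def _raw_spans_frame(narrations) -> pd.DataFrame:
    rows = []
    for narr in narrations:
        t = narr.transcript
        for s in narr.spans:
            rows.append(
                {
                    "participant_id": t.participant_id,
                    "picture_id": t.picture_id,
                    "start": s.start,
                    "end": s.end,
                    "head_lemma": s.head_lemma,
                    "is_pronoun": int(s.is_pronoun),
                    "is_null_subject": int(s.is_null_subject),
                    "anaphoric": "" if s.manual_flags.anaphoric is None else int(s.manual_flags.anaphoric),
                    "generic": "" if s.manual_flags.generic is None else int(s.manual_flags.generic),
                    "anomaly": int(s.manual_flags.anomaly),
                }
            )
    return pd.DataFrame(rows)


def _spans_from_frame(df: pd.DataFrame) -> dict[tuple[str, int], list[NPSpan]]:
    def opt(v):
        return None if (pd.isna(v) or v == "") else bool(int(v))

    out: dict[tuple[str, int], list[NPSpan]] = {}
    for row in df.itertuples(index=False):
        key = (str(row.participant_id), int(row.picture_id))
        out.setdefault(key, []).append(
            NPSpan(
                start=int(row.start),
                end=int(row.end),
                head_lemma=str(row.head_lemma) if not pd.isna(row.head_lemma) else "",
                is_pronoun=bool(int(row.is_pronoun)),
                is_null_subject=bool(int(row.is_null_subject)),
                manual_flags=ManualFlags(
                    anaphoric=opt(row.anaphoric),
                    generic=opt(row.generic),
                    anomaly=bool(int(row.anomaly)),
                ),
            )
        )
    return out


def dynamics_table(
    annotations: list[AnnotationSet],
    n_tokens_by_narration: dict[tuple[str, int], int],
    n_sim: int,
    alpha: float,
    seed: int,
    method: str,
    min_gaps: int = 8,
    jitter: bool = True,
) -> pd.DataFrame:
    """Group x macro-type arrival summary: mean distance and both
    Monte-Carlo exponentiality readouts."""
    rows = []
    for m_i, macro in enumerate(MACRO_TYPES):
        samples = group_gap_samples(annotations, macro, n_tokens_by_narration)
        for g_i, (grp, sample) in enumerate(sorted(samples.items())):
            res = exponentiality_test(
                sample,
                n_sim=n_sim,
                alpha=alpha,
                seed=seed + 1000 * m_i + g_i,
                method=method,
                min_gaps=min_gaps,
                jitter=jitter,
            )
            rows.append(
                {
                    "group": grp,
                    "macro_type": macro,
                    "n_gaps": res.n_gaps,
                    "mean_distance": res.mean_gap,
                    "lambda_hat": res.lambda_hat,
                    "fraction_significant": res.fraction_significant,
                    "mc_p": res.mc_p,
                    "rejected": res.rejected,
                    "insufficient": res.insufficient,
                }
            )
    return pd.DataFrame(rows)


def semantics_table(ts: TranscriptSet, seed: int, dim: int = 64) -> pd.DataFrame:
    """Per-narration similarity, pseudo-perplexity and image-text
    similarity under the deterministic stub provider."""
    provider = stub_provider(seed=seed, dim=dim)
    rows = []
    for t in ts:
        processed = preprocess_for_similarity(t)
        emb = provider.embed_tokens(processed)
        sim = consecutive_cosine_similarity(emb) if emb.n >= 2 else None
        full_surfaces = [tok.surface for tok in t.tokens if not tok.is_punct]
        ppl = (
            pseudo_perplexity(provider.token_probabilities(full_surfaces))
            if full_surfaces
            else None
        )
        image_vec = provider.embed_image(f"picture{t.picture_id}")
        utterances, current = [], []
        for tok in t.tokens:
            if tok.is_punct:
                if current:
                    utterances.append(" ".join(current))
                    current = []
            else:
                current.append(tok.surface)
        if current:
            utterances.append(" ".join(current))
        img2txt = (
            image_text_similarity(
                image_vec, [provider.embed_text(u) for u in utterances]
            )
            if utterances
            else None
        )
        rows.append(
            {
                "participant_id": t.participant_id,
                "group": t.group,
                "picture_id": t.picture_id,
                "n_tokens_processed": emb.n,
                "similarity": sim,
                "pseudo_perplexity": ppl,
                "img2txt_similarity": img2txt,
            }
        )
    return pd.DataFrame(rows)


OUTCOMES = [c.value for c in NPCategory] + ["anomalies"]


def fit_tables(
    counts: pd.DataFrame, semantics: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Poisson rate models per outcome and a GEE linking similarity to
    referential rates, both with BH q-values per model family."""
    pois_rows = []
    for outcome in OUTCOMES:
        if counts[outcome].sum() == 0:
            continue
        design = build_design(counts)
        fit = poisson_glm_offset(
            counts[outcome].to_numpy(),
            np.log(counts["word_count"].to_numpy(dtype=float)),
            design,
            fdr_family=outcome,
        )
        tab = fit.table()
        tab.insert(0, "outcome", outcome)
        pois_rows.append(tab)
    poisson_table = (
        pd.concat(pois_rows, ignore_index=True) if pois_rows else pd.DataFrame()
    )

    merged = counts.merge(semantics, on=["participant_id", "group", "picture_id"])
    merged = merged.dropna(subset=["similarity"])
    merged["all_definite_rate"] = merged["all_definite"] / merged["word_count"]
    merged["all_indefinite_rate"] = merged["all_indefinite"] / merged["word_count"]
    gee_table = pd.DataFrame()
    if merged["participant_id"].nunique() >= 2:
        design = build_design(
            merged, covariates=["all_definite_rate", "all_indefinite_rate"], center=True
        )
        gee = gee_gaussian_exchangeable(
            merged["similarity"].to_numpy(),
            design,
            merged["participant_id"].to_numpy(),
            fdr_family="similarity",
        )
        gee_table = gee.table()
        gee_table.insert(0, "outcome", "similarity")
        gee_table["rho_hat"] = gee.rho
        gee_table["n_clusters"] = gee.n_clusters
    return poisson_table, gee_table


REPORT_VARIABLES = [
    "word_count",
    "indefinite_dp",
    "definite_dp",
    "bare_anaphoric",
    "bare_specific",
    "bare_indefinite",
    "bare_generic",
    "bare_residual",
    "null_subject",
    "lexical_pronoun",
    "anomalies",
]


def report_tables(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-group participant-level means and SDs of the referential variables."""
    per_participant = counts.groupby(["group", "participant_id"], as_index=False)[
        REPORT_VARIABLES
    ].sum()
    rows = []
    for var in REPORT_VARIABLES:
        row = {"variable": var}
        for grp, sub in per_participant.groupby("group"):
            row[f"{grp}_mean"] = float(sub[var].mean())
            row[f"{grp}_sd"] = float(sub[var].std(ddof=1))
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages in dependency order and write a manifest.

    On stage failure the completed stages' outputs are left in place and
    the manifest records the failed stage before the error propagates.
    """
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(cfg),
        "version": __version__,
        "seed": cfg.seed,
        "stages": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    ts: TranscriptSet | None = None
    annotations: list[AnnotationSet] | None = None
    counts: pd.DataFrame | None = None
    sem: pd.DataFrame | None = None

    def record(stage: str, files: list[Path]) -> None:
        manifest["stages"][stage] = {
            "outputs": {f.name: _sha256(f) for f in files},
            "n_outputs": len(files),
        }

    def fail(stage: str, exc: Exception):
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise StageError(stage, str(exc)) from exc

    try:
        if "simulate" in cfg.stages:
            corpus = simulate_corpus(cfg.generator, seed=cfg.seed)
            ts = corpus.transcript_set
            annotations = corpus.annotations
            write_transcripts(ts, out / "corpus.jsonl")
            write_table(_raw_spans_frame(corpus.narrations), out / "spans.tsv")
            record("simulate", [out / "corpus.jsonl", out / "spans.tsv"])
    except StageError:
        raise
    except Exception as exc:
        fail("simulate", exc)

    try:
        if "annotate" in cfg.stages:
            if ts is None:
                corpus_path = cfg.corpus_path or out / "corpus.jsonl"
                spans_path = cfg.spans_path or out / "spans.tsv"
                if not Path(corpus_path).exists():
                    raise FileNotFoundError(f"corpus not found: {corpus_path}")
                ts = read_transcripts(corpus_path)
                spans_by_narr = _spans_from_frame(pd.read_csv(spans_path))
                annotations = [
                    annotate_transcript(
                        t, spans_by_narr.get((t.participant_id, t.picture_id), [])
                    )
                    for t in ts
                ]
            counts = counts_frame(annotations)
            write_table(spans_to_frame(annotations), out / "annotations.csv")
            write_table(counts, out / "counts.csv")
            record("annotate", [out / "annotations.csv", out / "counts.csv"])
    except StageError:
        raise
    except Exception as exc:
        fail("annotate", exc)

    def need(stage: str, what, name: str):
        if what is None:
            raise StageError(stage, f"missing dependency: {name} stage output")
        return what

    try:
        if "dynamics" in cfg.stages:
            annotations = need("dynamics", annotations, "annotate")
            ts = need("dynamics", ts, "corpus")
            n_tok = {(t.participant_id, t.picture_id): t.n_tokens for t in ts}
            dyn = dynamics_table(
                annotations,
                n_tok,
                n_sim=cfg.n_sim,
                alpha=cfg.alpha,
                seed=cfg.seed,
                method=cfg.arrival_method,
                min_gaps=cfg.min_gaps,
                jitter=cfg.jitter,
            )
            write_table(dyn, out / "dynamics.csv")
            record("dynamics", [out / "dynamics.csv"])
    except StageError as exc:
        fail(getattr(exc, "stage", "dynamics"), exc)
    except Exception as exc:
        fail("dynamics", exc)

    try:
        if "semantics" in cfg.stages:
            ts = need("semantics", ts, "corpus")
            sem = semantics_table(ts, seed=cfg.seed, dim=cfg.provider_dim)
            write_table(sem, out / "semantics.csv")
            record("semantics", [out / "semantics.csv"])
    except StageError as exc:
        fail(getattr(exc, "stage", "semantics"), exc)
    except Exception as exc:
        fail("semantics", exc)

    try:
        if "fit" in cfg.stages:
            counts = need("fit", counts, "annotate")
            sem = need("fit", sem, "semantics")
            poisson_table, gee_table = fit_tables(counts, sem)
            write_table(poisson_table, out / "fit_poisson.csv")
            write_table(gee_table, out / "fit_gee.csv")
            record("fit", [out / "fit_poisson.csv", out / "fit_gee.csv"])
    except StageError as exc:
        fail(getattr(exc, "stage", "fit"), exc)
    except Exception as exc:
        fail("fit", exc)

    try:
        if "report" in cfg.stages:
            counts = need("report", counts, "annotate")
            write_table(report_tables(counts), out / "report_descriptives.csv")
            record("report", [out / "report_descriptives.csv"])
    except StageError as exc:
        fail(getattr(exc, "stage", "report"), exc)
    except Exception as exc:
        fail("report", exc)

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
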