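"""End-to-end wiring: geolocate → aggregate → detect → alert files.

Alerts are written to CSV and JSON Lines files (this deployment has no
mail transport; the alert record carries the same fields an email alert
would: date, hour, topic, region, top words, tweet count, trusted-user
percentage and the configuration snapshot that produced the signal).
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .aggregate import (
    CountSeries,
    LocatedTweet,
    aggregate_counts,
    continent_map,
    default_stop_words,
    regions_for,
    write_series_csv,
)
from .config import PipelineConfig
from .detect import Alert, Signal, build_alert, detect_signals
from .evaluate import (
    AUTOMATED,
    MANUAL,
    AlertTriage,
    GeoAnnotation,
    dedup_events,
    geolocation_accuracy,
    ira,
    paired_time_diffs,
    ppv_general,
    ppv_specific,
    timeliness,
    wald_ci,
    wilcoxon_signed_rank,
)
from .geo import (
    CandidateClassifier,
    ClassifierParams,
    GazetteerEntry,
    GazetteerIndex,
    GeoMatch,
    build_index,
    geolocate_tweet,
    geolocate_user,
    load_geonames,
    train_candidate_classifier,
)
from ._text import tokens
from .stream import TweetRecord, read_tweets

__all__ = [
    "load_gazetteer",
    "load_common_words",
    "build_geo_resources",
    "geolocate_records",
    "run_pipeline",
    "run_evaluation",
    "write_alerts",
]

log = logging.getLogger("tweetwarn")


def load_gazetteer(config: PipelineConfig) -> list[GazetteerEntry]:
    if config.gazetteer_path is not None:
        return load_geonames(config.gazetteer_path)
    with resources.as_file(
        resources.files("tweetwarn.data").joinpath("gazetteer_toy.tsv")
    ) as p:
        return load_geonames(p)


def load_common_words(config: PipelineConfig) -> list[str]:
    if config.common_words_path is not None:
        text = Path(config.common_words_path).read_text(encoding="utf-8")
    else:
        text = resources.files("tweetwarn.data").joinpath("common_words.txt").read_text()
    return [w for w in text.split() if w]


def build_geo_resources(
    config: PipelineConfig,
) -> tuple[list[GazetteerEntry], CandidateClassifier, GazetteerIndex]:
    """Load the gazetteer, train the default candidate classifier, build the index.

    Positives are the tokens of all gazetteer names and alternate names;
    negatives are the bundled common-word list minus any token that is also
    a place-name token (the two classes must be disjoint).
    """
    entries = load_gazetteer(config)
    positives: set[str] = set()
    for e in entries:
        positives.update(tokens(e.name))
        for alt in e.alt_names:
            positives.update(tokens(alt))
    negatives = [w for w in load_common_words(config) if w.casefold() not in positives]
    classifier = train_candidate_classifier(
        sorted(positives), negatives, ClassifierParams(seed=config.seed)
    )
    index = build_index(entries)
    return entries, classifier, index


def geolocate_records(
    records: Sequence[TweetRecord],
    classifier: CandidateClassifier,
    index: GazetteerIndex,
    min_score: float = 10.0,
    min_candidate_score: float = 0.5,
) -> list[LocatedTweet]:
    located = []
    for rec in records:
        tm = geolocate_tweet(rec, classifier, index, min_score, min_candidate_score)
        um = geolocate_user(rec, classifier, index, min_score, min_candidate_score)
        located.append(LocatedTweet(record=rec, tweet_match=tm, user_match=um))
    return located


def _alert_rows(alerts: Sequence[Alert]) -> list[dict]:
    rows = []
    for a in alerts:
        rows.append(
            {
                "date": a.date.isoformat(),
                "hour": a.hour,
                "topic": a.topic,
                "region": a.region,
                "top_words": ";".join(w.word for w in a.top_words),
                "tweet_count": a.tweet_count,
                "trusted_pct": a.trusted_pct,
                "alpha": a.config.alpha,
                "baseline_days": a.config.baseline_days,
                "downweight_strength": a.config.downweight_strength,
            }
        )
    return rows


def write_alerts(alerts: Sequence[Alert], out_dir: Path) -> tuple[Path, Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = _alert_rows(alerts)
    csv_path = out_dir / "alerts.csv"
    pd.DataFrame(
        rows,
        columns=[
            "date",
            "hour",
            "topic",
            "region",
            "top_words",
            "tweet_count",
            "trusted_pct",
            "alpha",
            "baseline_days",
            "downweight_strength",
        ],
    ).to_csv(csv_path, index=False)
    jsonl_path = out_dir / "alerts.jsonl"
    with open(jsonl_path, "w", encoding="utf-8") as fh:
        for row in rows:
            fh.write(json.dumps(row, ensure_ascii=False) + "\n")
    return csv_path, jsonl_path


def run_pipeline(
    config: PipelineConfig,
    input_path: str | Path,
    as_of: dt.datetime,
) -> tuple[dict[tuple[str, str], CountSeries], list[Alert]]:
    """Execute the full chain on a stream file and write count/alert files."""
    try:
        records = read_tweets(input_path)
    except ValueError as exc:
        raise ValueError(f"stream stage: {exc}") from exc
    log.info("read %d records from %s", len(records), input_path)

    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not records:
        write_series_csv({}, out_dir / "counts.csv")
        write_alerts([], out_dir)
        return {}, []

    entries, classifier, index = build_geo_resources(config)
    located = geolocate_records(
        records, classifier, index, config.min_score, config.min_candidate_score
    )
    n_located = sum(1 for lt in located if lt.resolved_country)
    log.info("geolocate: %d/%d records resolved to a country", n_located, len(located))

    series = aggregate_counts(located)
    write_series_csv(series, out_dir / "counts.csv")
    log.info("aggregate: %d topic×region series", len(series))

    # records per (topic, region, date) for alert assembly
    cmap = continent_map()
    cell_records: dict[tuple[str, str, dt.date], list[TweetRecord]] = {}
    for lt in located:
        country = lt.resolved_country
        regions = regions_for(country, cmap) if country else ["WORLD"]
        for region in regions:
            cell_records.setdefault((lt.record.topic, region, lt.record.date), []).append(lt.record)

    stop = [default_stop_words(config.languages)]
    alerts: list[Alert] = []
    signals: list[Signal] = []
    for (topic, region), cs in sorted(series.items()):
        sig_config = config.signal_config_for(topic)
        past = [d for d in cs.counts.index if d < as_of.date()]
        if len(past) < sig_config.baseline_days:
            continue
        for sig in detect_signals(cs, sig_config, as_of):
            signals.append(sig)
            recs = cell_records.get((topic, region, sig.date), [])
            alerts.append(build_alert(sig, recs, stop_lists=stop))
    log.info("detect: %d signals at %s", len(signals), as_of.isoformat())
    write_alerts(alerts, out_dir)
    return series, alerts


# ---------------------------------------------------------------------------
# Evaluation report


def _annotations_from_frame(frame: pd.DataFrame) -> list[GeoAnnotation]:
    required = {"tweet_id", "rater", "gold_country", "gold_admin1", "pred_country", "pred_admin1"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"annotation table missing column(s): {sorted(missing)}")
    out = []
    for row in frame.itertuples(index=False):
        pred = None
        pc = getattr(row, "pred_country")
        if isinstance(pc, str) and pc:
            pa = getattr(row, "pred_admin1")
            score = float(getattr(row, "pred_score", 0.0) or 0.0)
            pred = GeoMatch(
                entry_id=-1,
                match_score=score,
                source="tweet_text",
                country=pc,
                admin1=pa if isinstance(pa, str) else "",
            )
        gc = getattr(row, "gold_country")
        ga = getattr(row, "gold_admin1")
        out.append(
            GeoAnnotation(
                tweet_id=str(getattr(row, "tweet_id")),
                rater=str(getattr(row, "rater")),
                gold_country=gc if isinstance(gc, str) and gc else None,
                gold_admin1=ga if isinstance(ga, str) and ga else None,
                predicted=pred,
            )
        )
    return out


def _triage_from_frame(frame: pd.DataFrame) -> list[AlertTriage]:
    required = {"alert_id", "status", "detected_by", "validation_time", "topic", "subtopic"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"triage table missing column(s): {sorted(missing)}")
    out = []
    for row in frame.itertuples(index=False):
        methods = getattr(row, "detected_by")
        detected = frozenset(
            m for m in (methods.split(";") if isinstance(methods, str) else []) if m
        )
        vt = getattr(row, "validation_time")
        out.append(
            AlertTriage(
                alert_id=str(getattr(row, "alert_id")),
                status=getattr(row, "status"),
                detected_by=detected,
                validation_time=(
                    dt.datetime.fromisoformat(vt) if isinstance(vt, str) and vt else None
                ),
                topic=str(getattr(row, "topic") or ""),
                subtopic=str(getattr(row, "subtopic") or ""),
            )
        )
    return out


def run_evaluation(
    config: PipelineConfig,
    annotations_path: Optional[str | Path] = None,
    triage_path: Optional[str | Path] = None,
    score_threshold: Optional[float] = None,
) -> dict:
    """Build the evaluation report from annotation/triage tables.

    The geolocation block is stratified into all tweets vs tweets whose
    prediction score exceeds the acceptance threshold; the signal block
    reports general/specific PPV, per-arm inter-rater agreement with Wald
    CIs, and timeliness of common unique events with the one-sided
    Wilcoxon signed-rank p-value.
    """
    report: dict = {}
    threshold = config.min_score if score_threshold is None else score_threshold

    if annotations_path is not None:
        frame = pd.read_csv(annotations_path, dtype=str, keep_default_na=False)
        if "pred_score" in frame.columns:
            frame["pred_score"] = pd.to_numeric(frame["pred_score"], errors="coerce").fillna(0.0)
        annotations = _annotations_from_frame(frame)
        geo_block: dict = {}
        for stratum_name, anns in (
            ("all", annotations),
            (
                f"score_gt_{threshold:g}",
                [
                    a
                    for a in annotations
                    if a.predicted is None or a.predicted.match_score > threshold
                ],
            ),
        ):
            levels = {}
            for level in ("national", "subnational"):
                acc, counts, metrics = geolocation_accuracy(anns, level)
                levels[level] = {
                    "n": len({a.tweet_id for a in anns}),
                    "accuracy": acc,
                    "confusion": vars(counts).copy(),
                    "metrics": vars(metrics).copy(),
                }
            geo_block[stratum_name] = levels
        report["geolocation"] = geo_block

    if triage_path is not None:
        triaged = _triage_from_frame(pd.read_csv(triage_path, dtype=str, keep_default_na=False))
        n_events = sum(1 for t in triaged if t.status == "event")
        n_false = sum(1 for t in triaged if t.status == "false_signal")
        n_not_eval = sum(1 for t in triaged if t.status == "not_evaluated")
        evaluated = [t for t in triaged if t.status != "not_evaluated"]
        n_eval = len(evaluated)
        signal_block: dict = {
            "n_alerts": len(triaged),
            "n_events": n_events,
            "n_false_signals": n_false,
            "n_not_evaluated": n_not_eval,
            "ppv_general": ppv_general(n_events, n_false, n_not_eval),
            "ppv_specific": ppv_specific(n_events, n_false),
        }
        for arm in (AUTOMATED, MANUAL):
            detected = sum(1 for t in evaluated if arm in t.detected_by)
            if n_eval:
                lo, hi = wald_ci(detected, n_eval)
                signal_block[f"ira_{arm}"] = ira(detected, n_eval)
                signal_block[f"ira_{arm}_ci"] = (lo, hi)
        events = dedup_events(triaged)
        diffs = paired_time_diffs(events)
        signal_block["n_unique_events"] = len(events)
        signal_block["n_common_events"] = len(diffs)
        if diffs:
            med, q1, q3 = timeliness(diffs)
            w, p = wilcoxon_signed_rank(diffs, alternative="less")
            signal_block["timeliness_median_h"] = med
            signal_block["timeliness_iqr_h"] = (q1, q3)
            signal_block["wilcoxon_w"] = w
            signal_block["wilcoxon_p_less"] = p
        report["signals"] = signal_block

    return report


def report_to_text(report: dict) -> str:
    """Human-readable rendering of the evaluation report."""
    lines: list[str] = []
    geo = report.get("geolocation")
    if geo:
        lines.append("Geolocation evaluation")
        for stratum, levels in geo.items():
            lines.append(f"  stratum: {stratum}")
            for level, block in levels.items():
                m = block["metrics"]
                lines.append(
                    f"    {level}: accuracy {block['accuracy']:.1f}%  "
                    f"sens {m['sensitivity']:.1f}%  spec {m['specificity']:.1f}%  "
                    f"ppv {m['ppv']:.1f}%  npv {m['npv']:.1f}%  prev {m['prevalence']:.1f}%"
                )
    sig = report.get("signals")
    if sig:
        lines.append("Signal-detection evaluation")
        lines.append(
            f"  alerts {sig['n_alerts']}  events {sig['n_events']}  "
            f"false signals {sig['n_false_signals']}  not evaluated {sig['n_not_evaluated']}"
        )
        lines.append(
            f"  PPV_g {sig['ppv_general']:.1f}%  PPV_s {sig['ppv_specific']:.1f}%"
        )
        for arm in (AUTOMATED, MANUAL):
            key = f"ira_{arm}"
            if key in sig:
                lo, hi = sig[f"{key}_ci"]
                lines.append(f"  IRA {arm} {sig[key]:.1f}% (95% CI {lo:.1f}-{hi:.1f})")
        if "timeliness_median_h" in sig:
            q1, q3 = sig["timeliness_iqr_h"]
            lines.append(
                f"  timeliness median {sig['timeliness_median_h']:.1f} h "
                f"(IQR {q1:.1f} to {q3:.1f}); Wilcoxon W+ {sig['wilcoxon_w']:.1f}, "
                f"one-sided p {sig['wilcoxon_p_less']:.4g}"
            )
    return "\n".join(lines) + "\n"
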