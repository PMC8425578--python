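"""Config-driven orchestration of all preprocessing stages (composer).

Canonical stage order: buffer trim (scallop front) -> demultiplex (anemone)
-> motif filter (rotifer) -> quality end-trim (scallop window) -> Q-threshold
filter (krill) -> adapter trim (porifera).  The order is fixed apart from an
optional swap of end-trimming and threshold filtering; other orders require
standalone invocation.  Paired and single-end populations are tracked
separately throughout: a read whose mate is removed at any stage drops into
a single-end lineage that still traverses every remaining stage.  Every
stage appends a manifest entry with input/output/discard counts so a
conservation ledger (reads in == reads out + discards) can be checked at
any point, and QC count matrices can be emitted per stage.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Callable

from . import anemone, crinoid, krill, porifera, rotifer, scallop
from .anemone import BarcodeScheme, load_barcode_scheme
from .fastq_io import count_records
from .krill import ThresholdSpec
from .rotifer import MotifSet
from .scallop import TrimSpec


@dataclass
class PipelineConfig:
    r1: str
    r2: str | None = None
    scheme: BarcodeScheme | None = None
    barcodes_path: str | None = None
    front_trim: int = 6
    mismatch: int = 0
    r1_motifs: list[str] = field(default_factory=list)
    r2_motifs: list[str] = field(default_factory=list)
    end_window: int = 0  # 0 disables quality end-trimming
    end_q: int = 30
    q: int | None = None  # None disables threshold filtering
    p: int = 90
    # adapter trimming: per-sample templates (pipeline mode) or a global list
    adapter_map: dict[str, tuple[list[str], list[str]]] = field(default_factory=dict)
    adapters_r1: list[str] = field(default_factory=list)
    adapters_r2: list[str] = field(default_factory=list)
    k: int = porifera.DEFAULT_K
    rounds: int = porifera.DEFAULT_ROUNDS
    votes: int = porifera.DEFAULT_VOTES
    t: int | None = None
    min_overlap: int = porifera.DEFAULT_MIN_OVERLAP
    min_len: int = porifera.DEFAULT_MIN_LEN
    endtrim_before_krill: bool = True
    qc: bool = False  # crinoid summaries after each stage
    outdir: str = "composer_out"
    seed: int = 0

    def resolve_scheme(self) -> BarcodeScheme:
        if self.scheme is None:
            if self.barcodes_path is None:
                raise ValueError("config needs a barcode scheme or barcodes_path")
            self.scheme = load_barcode_scheme(self.barcodes_path)
        return self.scheme


def parse_config(path: str | os.PathLike) -> PipelineConfig:
    """Parse a flat key=value config file (lists comma-separated, '#' comments)."""
    kv: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            kv[key.strip()] = val.strip()
    def get_list(key: str) -> list[str]:
        return [x for x in kv.get(key, "").split(",") if x]
    cfg = PipelineConfig(
        r1=kv["r1"],
        r2=kv.get("r2") or None,
        barcodes_path=kv.get("barcodes") or None,
        front_trim=int(kv.get("front_trim", 6)),
        mismatch=int(kv.get("mismatch", 0)),
        r1_motifs=get_list("r1_motifs"),
        r2_motifs=get_list("r2_motifs"),
        end_window=int(kv.get("end_window", 0)),
        end_q=int(kv.get("end_q", 30)),
        q=int(kv["q"]) if kv.get("q") else None,
        p=int(kv.get("p", 90)),
        adapters_r1=get_list("adapters_r1"),
        adapters_r2=get_list("adapters_r2"),
        k=int(kv.get("k", porifera.DEFAULT_K)),
        rounds=int(kv.get("rounds", porifera.DEFAULT_ROUNDS)),
        votes=int(kv.get("votes", porifera.DEFAULT_VOTES)),
        t=int(kv["t"]) if kv.get("t") else None,
        min_overlap=int(kv.get("min_overlap", porifera.DEFAULT_MIN_OVERLAP)),
        min_len=int(kv.get("min_len", porifera.DEFAULT_MIN_LEN)),
        endtrim_before_krill=kv.get("endtrim_before_krill", "true").lower() != "false",
        qc=kv.get("qc", "false").lower() == "true",
        outdir=kv.get("outdir", "composer_out"),
        seed=int(kv.get("seed", 0)),
    )
    return cfg


def walkthrough_prompt(
    stage: str,
    params: dict,
    summary: str = "",
    answers: dict[str, str] | None = None,
    input_fn: Callable[[str], str] | None = None,
) -> dict:
    """Confirm or update a stage's parameters before it runs.

    Scripted mode passes ``answers`` mapping ``stage.param`` to new values
    (missing keys keep defaults); interactive mode prompts via ``input_fn``
    (empty input accepts the default).  A non-interactive run without an
    answers mapping aborts.
    """
    updated = dict(params)
    if answers is not None:
        for key, val in params.items():
            raw = answers.get(f"{stage}.{key}")
            if raw is not None and raw != "":
                updated[key] = type(val)(raw) if val is not None else raw
        return updated
    if input_fn is None:
        raise RuntimeError(
            f"walkthrough mode for stage {stage!r} needs an interactive terminal "
            "or a scripted answers file"
        )
    if summary:
        print(summary)
    for key, val in params.items():
        while True:
            raw = input_fn(f"[{stage}] {key} [{val}]: ").strip()
            if raw == "":
                break
            try:
                updated[key] = type(val)(raw) if val is not None else raw
                break
            except (TypeError, ValueError):
                print(f"invalid value {raw!r} for {key}, try again")
    return updated


def _qc(cfg: PipelineConfig, stage_dir: str, fastq_path: str) -> None:
    if cfg.qc and os.path.exists(fastq_path) and os.path.getsize(fastq_path):
        crinoid.summarize_to_files(fastq_path, os.path.join(stage_dir, "qc"))


def run_pipeline(
    cfg: PipelineConfig,
    walkthrough: bool = False,
    answers: dict[str, str] | None = None,
    input_fn: Callable[[str], str] | None = None,
) -> dict:
    """Execute the enabled stages in canonical order; return the manifest.

    The manifest lists one entry per (stage, population) with file paths and
    conservation counts; final per-sample outputs land in
    ``<outdir>/final/`` with single-end survivors in ``<outdir>/final/se/``.
    """
    scheme = cfg.resolve_scheme()
    root = os.fspath(cfg.outdir)
    os.makedirs(root, exist_ok=True)
    manifest: list[dict] = []
    paired = cfg.r2 is not None

    def maybe_walk(stage: str, params: dict) -> dict:
        if not walkthrough:
            return params
        return walkthrough_prompt(stage, params, answers=answers, input_fn=input_fn)

    # stage 1: buffer trim -------------------------------------------------
    params = maybe_walk("scallop_front", {"front": cfg.front_trim})
    stage_dir = os.path.join(root, "01_scallop")
    res = scallop.trim_file(
        cfg.r1, cfg.r2, TrimSpec(front=params["front"]), stage_dir, prefix="buffer"
    )
    manifest.append({"stage": "scallop_front", "sample": "*", **_counts(res)})
    _qc(cfg, stage_dir, res["paths"]["r1"])
    r1_cur, r2_cur = res["paths"]["r1"], res["paths"].get("r2")

    # stage 2: demultiplex -------------------------------------------------
    params = maybe_walk("anemone", {"mismatch": cfg.mismatch})
    stage_dir = os.path.join(root, "02_anemone")
    res = anemone.demultiplex(
        r1_cur, r2_cur, scheme, max_m=params["mismatch"], outdir=stage_dir
    )
    manifest.append(
        {
            "stage": "anemone",
            "sample": "*",
            "reads_in": res["reads_in"],
            "reads_out": res["reads_assigned"] + res["reads_unknown"],
            "reads_discarded": 0,
            "reads_assigned": res["reads_assigned"],
            "reads_unknown": res["reads_unknown"],
        }
    )

    # per-sample chain -----------------------------------------------------
    motifs = MotifSet(cfg.r1_motifs, cfg.r2_motifs)
    final_dir = os.path.join(root, "final")
    se_final = os.path.join(final_dir, "se")
    os.makedirs(se_final, exist_ok=True)

    def stage_list() -> list[str]:
        stages = []
        if cfg.r1_motifs:
            stages.append("rotifer")
        mid = []
        if cfg.end_window:
            mid.append("scallop_end")
        if cfg.q is not None:
            mid.append("krill")
        if not cfg.endtrim_before_krill:
            mid.reverse()
        stages.extend(mid)
        if cfg.adapter_map or cfg.adapters_r1:
            stages.append("porifera")
        return stages

    stages = stage_list()
    walk_params: dict[str, dict] = {}
    if "rotifer" in stages:
        walk_params["rotifer"] = maybe_walk("rotifer", {})
    if "scallop_end" in stages:
        walk_params["scallop_end"] = maybe_walk(
            "scallop_end", {"window": cfg.end_window, "end_q": cfg.end_q}
        )
    if "krill" in stages:
        walk_params["krill"] = maybe_walk("krill", {"q": cfg.q, "p": cfg.p})
    if "porifera" in stages:
        walk_params["porifera"] = maybe_walk(
            "porifera",
            {"k": cfg.k, "rounds": cfg.rounds, "votes": cfg.votes,
             "min_overlap": cfg.min_overlap, "min_len": cfg.min_len},
        )

    def sample_index(sample: str) -> tuple:
        if cfg.adapter_map:
            a1, a2 = cfg.adapter_map[sample]
        else:
            a1, a2 = cfg.adapters_r1, cfg.adapters_r2 or cfg.adapters_r1
        pk = walk_params["porifera"]["k"]
        return porifera.build_index(list(a1), k=pk), porifera.build_index(list(a2), k=pk)

    def run_paired(stage: str, sample: str, r1p: str, r2p: str, outdir: str):
        """Returns (pass_r1, pass_r2, [(side, se_path)], entry)."""
        if stage == "rotifer":
            res = rotifer.filter_motif(r1p, r2p, motifs, outdir, prefix=sample)
            se = [("r1", res["paths"]["se_r1"]), ("r2", res["paths"]["se_r2"])]
            entry = {"reads_in": res["reads_in"], "reads_out": res["reads_in"],
                     "reads_discarded": 0, "reads_fail": res["reads_fail"]}
            return res["paths"]["pass_r1"], res["paths"]["pass_r2"], se, entry
        if stage == "scallop_end":
            wp = walk_params[stage]
            res = scallop.trim_file(
                r1p, r2p, TrimSpec(window=wp["window"], end_q=wp["end_q"]),
                outdir, prefix=sample,
            )
            se = [("r1", res["paths"]["se_r1"]), ("r2", res["paths"]["se_r2"])]
            return res["paths"]["r1"], res["paths"]["r2"], se, _counts(res)
        if stage == "krill":
            wp = walk_params[stage]
            res = krill.filter_file(r1p, r2p, ThresholdSpec(wp["q"], wp["p"]), outdir, prefix=sample)
            se = [("r1", res["paths"]["se_r1"]), ("r2", res["paths"]["se_r2"])]
            entry = {"reads_in": res["reads_in"], "reads_out": res["reads_in"],
                     "reads_discarded": 0, "reads_fail": res["reads_fail"]}
            return res["paths"]["pass_r1"], res["paths"]["pass_r2"], se, entry
        if stage == "porifera":
            wp = walk_params[stage]
            idx1, idx2 = sample_index(sample)
            res = porifera.trim_adapters(
                r1p, r2p, idx1, idx2, m=wp["votes"], r=wp["rounds"],
                t=cfg.t, min_overlap=wp["min_overlap"], min_len=wp["min_len"],
                outdir=outdir, prefix=sample,
            )
            se = [("r1", res["paths"]["se_r1"]), ("r2", res["paths"]["se_r2"])]
            return res["paths"]["r1"], res["paths"]["r2"], se, _counts(res)
        raise ValueError(stage)

    def run_single(stage: str, sample: str, side: str, path: str, outdir: str):
        prefix = f"se.{sample}.{side}"
        if stage == "rotifer":
            mlist = motifs.r1_motifs if side == "r1" else motifs.r2_motifs
            res = rotifer.filter_motif(path, None, MotifSet(mlist, []), outdir, prefix=prefix)
            return res["paths"]["pass_r1"], {"reads_in": res["reads_in"],
                                             "reads_out": res["reads_in"],
                                             "reads_discarded": 0}
        if stage == "scallop_end":
            wp = walk_params[stage]
            res = scallop.trim_file(path, None, TrimSpec(window=wp["window"], end_q=wp["end_q"]),
                                    outdir, prefix=prefix)
            return res["paths"]["r1"], _counts(res)
        if stage == "krill":
            wp = walk_params[stage]
            res = krill.filter_file(path, None, ThresholdSpec(wp["q"], wp["p"]), outdir, prefix=prefix)
            return res["paths"]["pass_r1"], {"reads_in": res["reads_in"],
                                             "reads_out": res["reads_in"],
                                             "reads_discarded": 0}
        if stage == "porifera":
            wp = walk_params[stage]
            idx1, idx2 = sample_index(sample)
            res = porifera.trim_adapters(
                path, None, idx1 if side == "r1" else idx2, m=wp["votes"],
                r=wp["rounds"], t=cfg.t, min_overlap=wp["min_overlap"],
                min_len=wp["min_len"], outdir=outdir, prefix=prefix,
            )
            return res["paths"]["r1"], _counts(res)
        raise ValueError(stage)

    sample_final: dict[str, tuple[str, str]] = {}
    for sample in scheme.samples():
        r1p = os.path.join(root, "02_anemone", f"{sample}.R1.fastq")
        r2p = os.path.join(root, "02_anemone", f"{sample}.R2.fastq") if paired else None
        if not os.path.exists(r1p) or count_records(r1p) == 0:
            continue
        se_queue: list[tuple[str, str, int]] = []  # (side, path, next stage idx)
        for si, stage in enumerate(stages):
            outdir = os.path.join(root, f"{si + 3:02d}_{stage}", sample)
            if paired:
                r1p, r2p, se_files, entry = run_paired(stage, sample, r1p, r2p, outdir)
                for side, sp in se_files:
                    if os.path.exists(sp) and os.path.getsize(sp):
                        se_queue.append((side, sp, si + 1))
            else:
                r1p, entry = run_single(stage, sample, "r1", r1p, outdir)
            manifest.append({"stage": stage, "sample": sample, **entry})
            _qc(cfg, outdir, r1p)
        # single-end lineages traverse the remaining stages
        for side, sp, next_idx in se_queue:
            cur = sp
            for sj in range(next_idx, len(stages)):
                stage = stages[sj]
                outdir = os.path.join(root, f"{sj + 3:02d}_{stage}", sample)
                cur, entry = run_single(stage, sample, side, cur, outdir)
                manifest.append({"stage": f"{stage}(se)", "sample": sample, **entry})
            dest = os.path.join(se_final, f"{sample}.{side.upper()}.fastq")
            _concat(cur, dest)
        sample_final[sample] = (r1p, r2p)
        _link_final(r1p, os.path.join(final_dir, f"{sample}.R1.fastq"))
        if paired and r2p:
            _link_final(r2p, os.path.join(final_dir, f"{sample}.R2.fastq"))

    result = {
        "manifest": manifest,
        "final_dir": final_dir,
        "samples": sample_final,
        "outdir": root,
    }
    write_manifest(manifest, os.path.join(root, "manifest.tsv"))
    return result


def _counts(res: dict) -> dict:
    return {
        "reads_in": res["reads_in"],
        "reads_out": res["reads_out"],
        "reads_discarded": res["reads_discarded"],
    }


def _concat(src: str, dest: str) -> None:
    mode = "ab" if os.path.exists(dest) else "wb"
    with open(src, "rb") as s, open(dest, mode) as d:
        d.write(s.read())


def _link_final(src: str, dest: str) -> None:
    if os.path.exists(dest):
        os.remove(dest)
    with open(src, "rb") as s, open(dest, "wb") as d:
        d.write(s.read())


def write_manifest(manifest: list[dict], path: str) -> None:
    keys = ["stage", "sample", "reads_in", "reads_out", "reads_discarded"]
    extra = sorted({k for e in manifest for k in e} - set(keys))
    with open(path, "w") as fh:
        fh.write("\t".join(keys + extra) + "\n")
        for e in manifest:
            fh.write("\t".join(str(e.get(k, "")) for k in keys + extra) + "\n")


def check_conservation(manifest: list[dict]) -> bool:
    """Every stage entry must satisfy reads_in == reads_out + reads_discarded."""
    for e in manifest:
        out = e.get("reads_out", 0) + e.get("reads_discarded", 0)
        if e["reads_in"] != out:
            return False
    return True
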