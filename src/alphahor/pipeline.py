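"""End-to-end orchestration: detection -> typing -> MD/GRM -> HORs -> divergence.

Each stage writes its artifact into the output directory; a MANIFEST.json
records stage status and headline counts so partial runs are inspectable.
The configuration is echoed into the output directory as provenance; the
whole pipeline is deterministic for a fixed configuration and input.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import divstats, horstruct, monfind, montype, repeatmap, seqio

log = logging.getLogger("alphahor")


@dataclass
class PipelineConfig:
    fasta: str
    consensus: str
    out_dir: str
    max_divergence: float = monfind.DEFAULT_MAX_DIVERGENCE
    length_band: tuple[int, int] = monfind.DEFAULT_LENGTH_BAND
    gap_max: int = monfind.DEFAULT_GAP_MAX
    scan_both_strands: bool = False
    type_threshold: float = montype.DEFAULT_TYPE_THRESHOLD
    min_copies: int = horstruct.DEFAULT_MIN_COPIES
    support_fraction: float = horstruct.DEFAULT_SUPPORT_FRACTION
    min_peak_count: int = 10
    plots: bool = False

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def monomers_table(monomers: list[monfind.Monomer]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "index": [m.index for m in monomers],
            "seq_id": [m.interval.seq_id for m in monomers],
            "start": [m.interval.start for m in monomers],
            "end": [m.interval.end for m in monomers],
            "strand": [m.interval.strand for m in monomers],
            "length": [m.interval.length for m in monomers],
            "divergence_pct": [m.divergence_to_consensus for m in monomers],
            "sequence": [m.sequence for m in monomers],
        }
    )


def monomers_from_table(table: pd.DataFrame) -> list[monfind.Monomer]:
    return [
        monfind.Monomer(
            index=int(r["index"]),
            interval=seqio.Interval(
                str(r["seq_id"]), int(r["start"]), int(r["end"]), str(r["strand"])
            ),
            sequence=str(r["sequence"]),
            divergence_to_consensus=float(r["divergence_pct"]),
        )
        for _, r in table.iterrows()
    ]


def hors_table(arrays: list[horstruct.HORArray],
               monomers: list[monfind.Monomer]) -> pd.DataFrame:
    rows = []
    for aid, arr in enumerate(arrays):
        for copy in arr.copies:
            rows.append(
                {
                    "array_id": aid,
                    "period": arr.period,
                    "structure_class": arr.structure_class,
                    "copy_index": copy.copy_index,
                    "start": monomers[copy.start_index].interval.start,
                    "end": monomers[copy.end_index - 1].interval.end,
                    "start_monomer": copy.start_index,
                    "end_monomer": copy.end_index,
                    "status": copy.status,
                    "variant_label": copy.variant_label or "",
                    "type_sequence": ",".join(map(str, copy.type_sequence)),
                }
            )
    return pd.DataFrame(rows)


def run_all(config: PipelineConfig) -> Path:
    """Run every stage; returns the output directory.

    On a stage failure the exception propagates after MANIFEST.json is
    written with the failed stage name, so partial outputs stay usable.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json())
    manifest: dict = {"stages": [], "counts": {}}

    def finish(stage: str, error: str | None = None):
        manifest["stages"].append(
            {"stage": stage, "status": "failed" if error else "ok", "error": error}
        )
        (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))

    stage = "monfind"
    try:
        records = seqio.read_fasta(config.fasta)
        consensus = seqio.read_fasta(config.consensus)[0]
        monomers: list[monfind.Monomer] = []
        for rec in records:
            t0 = time.perf_counter()
            found = monfind.detect_monomers(
                rec,
                consensus,
                max_divergence=config.max_divergence,
                length_band=tuple(config.length_band),
                gap_max=config.gap_max,
                scan_both_strands=config.scan_both_strands,
            )
            offset = len(monomers)
            monomers.extend(
                dataclasses.replace(m, index=offset + m.index) for m in found
            )
            log.info(
                "monfind: %s -> %d monomers (%.2fs)",
                rec.id, len(found), time.perf_counter() - t0,
            )
        table = monomers_table(monomers)
        seqio.write_tsv(table, out / "monomers.tsv")
        seqio.write_bed(
            [m.interval for m in monomers],
            out / "monomers.bed",
            names=[f"m{m.index}" for m in monomers],
        )
        blocks = monfind.group_blocks(monomers, gap_max=config.gap_max)
        manifest["counts"]["monomers"] = len(monomers)
        manifest["counts"]["blocks"] = len(blocks)
        finish(stage)
    except Exception as exc:  # noqa: BLE001 — manifest must record the stage
        finish(stage, str(exc))
        raise

    stage = "montype"
    try:
        typed, types = montype.assign_types(monomers, config.type_threshold)
        table["type_id"] = [tm.type_id for tm in typed]
        seqio.write_tsv(table, out / "typed.tsv")
        seqio.write_fasta(
            [seqio.SequenceRecord(f"t{t.type_id}", t.representative) for t in types],
            out / "types.fasta",
        )
        manifest["counts"]["types"] = len(types)
        log.info("montype: %d types", len(types))
        finish(stage)
    except Exception as exc:  # noqa: BLE001
        finish(stage, str(exc))
        raise

    stage = "repeatmap"
    try:
        block_ranges = [(b.start_index, b.end_index) for b in blocks]
        md = repeatmap.compute_md(typed, blocks=block_ranges)
        seqio.write_tsv(
            pd.DataFrame(
                {
                    "monomer_index": [p.monomer_index for p in md],
                    "period": [p.period for p in md],
                }
            ),
            out / "md.tsv",
        )
        hist = repeatmap.grm_histogram(md)
        peaks = repeatmap.rank_peaks(hist, min_count=1)
        seqio.write_tsv(
            pd.DataFrame(
                {
                    "period": [p for p, _ in peaks],
                    "count": [c for _, c in peaks],
                    "rank": range(1, len(peaks) + 1),
                }
            ),
            out / "grm.tsv",
        )
        if config.plots:
            repeatmap.plot_grm(hist, out / "grm.png")
            repeatmap.plot_md(md, out / "md.png")
        manifest["counts"]["md_points"] = len(md)
        log.info("repeatmap: %d MD points, top peak %s", len(md), peaks[:1])
        finish(stage)
    except Exception as exc:  # noqa: BLE001
        finish(stage, str(exc))
        raise

    stage = "horstruct"
    try:
        arrays = horstruct.find_hors(
            typed, md,
            min_copies=config.min_copies,
            support_fraction=config.support_fraction,
            blocks=block_ranges,
        )
        htable = hors_table(arrays, monomers)
        seqio.write_tsv(htable, out / "hors.tsv")
        if len(htable):
            ivs, names = [], []
            for _, r in htable.sort_values(["start"]).iterrows():
                ivs.append(
                    seqio.Interval(
                        monomers[int(r["start_monomer"])].interval.seq_id,
                        int(r["start"]), int(r["end"]),
                    )
                )
                names.append(
                    f"a{r['array_id']}_{r['period']}mer_c{r['copy_index']}_{r['status']}"
                )
            seqio.write_bed(ivs, out / "hors.bed", names=names)
        scheme_dir = out / "schemes"
        scheme_dir.mkdir(exist_ok=True)
        for aid, arr in enumerate(arrays):
            scheme = horstruct.cascading_scheme(arr.canonical_sequence)
            (scheme_dir / f"array{aid}_{arr.period}mer.txt").write_text(
                scheme.render() + "\n"
            )
        manifest["counts"]["arrays"] = len(arrays)
        manifest["counts"]["copies"] = sum(len(a.copies) for a in arrays)
        manifest["counts"]["canonical_copies"] = sum(a.n_canonical for a in arrays)
        log.info(
            "horstruct: %d arrays, %d copies", len(arrays),
            manifest["counts"]["copies"],
        )
        finish(stage)
    except Exception as exc:  # noqa: BLE001
        finish(stage, str(exc))
        raise

    stage = "divstats"
    try:
        rep_of = {t.type_id: t.representative for t in types}
        report: dict = {"intra": {}, "inter": {}, "copies": {}}
        array_monomers: dict[int, list[str]] = {}
        for aid, arr in enumerate(arrays):
            distinct = list(dict.fromkeys(arr.canonical_sequence))
            mons = [rep_of[t] for t in distinct]
            array_monomers[aid] = mons
            if len(mons) >= 2:
                report["intra"][str(aid)] = divstats.intra_hor_divergence(mons).as_dict()
            canon_seqs = [
                "".join(monomers[i].sequence for i in range(c.start_index, c.end_index))
                for c in arr.copies
                if c.status == "canonical"
            ]
            if len(canon_seqs) >= 2:
                report["copies"][str(aid)] = divstats.copy_divergence(canon_seqs).as_dict()
        for a in array_monomers:
            for b in array_monomers:
                if a < b:
                    report["inter"][f"{a}-{b}"] = divstats.inter_hor_divergence(
                        array_monomers[a], array_monomers[b]
                    ).as_dict()
        (out / "divergence.json").write_text(json.dumps(report, indent=2))
        finish(stage)
    except Exception as exc:  # noqa: BLE001
        finish(stage, str(exc))
        raise

    return out
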