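"""Readers and writers for every on-disk format the toolkit touches.

All tabular formats are TSV with dot decimal separators and UNIX
newlines, matching pore-model file conventions:

* k-mer model: header ``kmer<TAB>level_mean``, one row per k-mer; extra
  columns are accepted and ignored.
* squiggle ensemble: long format, header
  ``squiggle_id<TAB>event_index<TAB>current`` with 0-based contiguous
  event indices per squiggle.
* gold squiggle: header ``event_index<TAB>current``.
* ground truth: header
  ``squiggle_id<TAB>gold_index<TAB>insertion_count<TAB>deleted``.

Currents are written with 17 significant digits so write/read round-trips
are exact at float64 precision.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .characterize import LengthModel, RateCurve, REFERENCE_RATE_CURVE, REFERENCE_TAIL, TailModel
from .dtw import EnsembleComparison, IndelProfile
from .errors import EmptyEnsembleError, FormatError
from .signal_model import Ensemble, GoldStandard, KmerModel, Squiggle
from .simulate import MockRecord, SimConfig

_FLOAT_FMT = "%.17g"


# ---------------------------------------------------------------------------
# sequences and k-mer models


def read_fasta(path, record_id: str | None = None) -> str:
    """Sequence of the first (or named) record of a FASTA file."""
    for rec in SeqIO.parse(str(path), "fasta"):
        if record_id is None or rec.id == record_id:
            return str(rec.seq)
    raise FormatError(f"no FASTA record {record_id!r} in {path}")


def read_kmer_model(path) -> KmerModel:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if "kmer" not in df.columns or "level_mean" not in df.columns:
        raise FormatError(f"{path}: expected columns 'kmer' and 'level_mean'")
    kmers = df["kmer"].astype(str).str.upper().str.replace("U", "T")
    k = len(kmers.iloc[0])
    return KmerModel(
        k=k,
        levels=dict(zip(kmers, df["level_mean"].astype(float))),
        model_id=Path(path).stem,
    )


def write_kmer_model(model: KmerModel, path) -> None:
    with open(path, "w") as fh:
        fh.write("kmer\tlevel_mean\n")
        for kmer in sorted(model.levels):
            fh.write(f"{kmer}\t{_FLOAT_FMT % model.levels[kmer]}\n")


# ---------------------------------------------------------------------------
# squiggles


def write_ensemble(ens: Ensemble, path) -> None:
    with open(path, "w") as fh:
        fh.write("squiggle_id\tevent_index\tcurrent\n")
        for s in ens:
            for i, v in enumerate(s.events):
                fh.write(f"{s.id}\t{i}\t{_FLOAT_FMT % v}\n")


def read_ensemble(path, normalized: bool = False) -> Ensemble:
    """Read a long-format ensemble TSV.

    ``normalized`` declares the normalization state of the stored events
    (the dialect itself does not record it).  Non-contiguous event indices
    raise a FormatError naming the squiggle and the offending line.
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if df.empty:
        raise EmptyEnsembleError(f"{path}: no squiggles")
    required = {"squiggle_id", "event_index", "current"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(required)}")
    squiggles = []
    for sid, grp in df.groupby("squiggle_id", sort=False):
        idx = grp["event_index"].to_numpy()
        expect = np.arange(idx.size)
        if not np.array_equal(idx, expect):
            bad = int(np.argmax(idx != expect))
            line = int(grp.index[bad]) + 2  # +1 header, +1 one-based
            raise FormatError(
                f"{path}:{line}: squiggle {sid!r} has non-contiguous "
                f"event_index ({idx[bad]} where {expect[bad]} expected)"
            )
        squiggles.append(
            Squiggle(id=str(sid), events=grp["current"].to_numpy(dtype=float),
                     normalized=normalized)
        )
    return Ensemble(squiggles=squiggles, provenance={"source": str(path)})


def write_gold(gold: GoldStandard, path) -> None:
    with open(path, "w") as fh:
        fh.write("event_index\tcurrent\n")
        for i, v in enumerate(gold.events):
            fh.write(f"{i}\t{_FLOAT_FMT % v}\n")


def read_gold(path, normalized: bool = False) -> GoldStandard:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if not {"event_index", "current"}.issubset(df.columns):
        raise FormatError(f"{path}: expected columns event_index, current")
    return GoldStandard(
        squiggle=Squiggle(
            id="gold", events=df["current"].to_numpy(dtype=float), normalized=normalized
        )
    )


def write_truth(records: list[MockRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("squiggle_id\tgold_index\tinsertion_count\tdeleted\n")
        for rec in records:
            for i, (c, d) in enumerate(zip(rec.insertion_counts, rec.deleted)):
                fh.write(f"{rec.squiggle.id}\t{i}\t{int(c)}\t{int(d)}\n")


# ---------------------------------------------------------------------------
# analysis outputs


def write_profile(profile: IndelProfile, path) -> None:
    """Indel profile as TSV: count, insertion mean/std, deletion mean/std (%)."""
    n = max(profile.insertion_mean.size, profile.deletion_mean.size)
    with open(path, "w") as fh:
        fh.write("count\tinsertion_mean\tinsertion_std\tdeletion_mean\tdeletion_std\n")
        for c in range(n):
            ins_m = profile.insertion_mean[c] * 100 if c < profile.insertion_mean.size else ""
            ins_s = profile.insertion_std[c] * 100 if c < profile.insertion_std.size else ""
            del_m = profile.deletion_mean[c] * 100 if c < profile.deletion_mean.size else ""
            del_s = profile.deletion_std[c] * 100 if c < profile.deletion_std.size else ""
            row = [c] + [("" if v == "" else f"{v:.4f}") for v in (ins_m, ins_s, del_m, del_s)]
            fh.write("\t".join(str(x) for x in row) + "\n")


def profile_summary(profile: IndelProfile, comparison: EnsembleComparison | None = None) -> dict:
    out = {
        "n_squiggles": profile.n_squiggles,
        "insertion_mean_pct": (profile.insertion_mean * 100).round(4).tolist(),
        "insertion_std_pct": (profile.insertion_std * 100).round(4).tolist(),
        "deletion_mean_pct": (profile.deletion_mean * 100).round(4).tolist(),
        "deletion_std_pct": (profile.deletion_std * 100).round(4).tolist(),
    }
    if comparison is not None:
        out["frechet_mean"] = comparison.mean_distance
        out["frechet_std"] = comparison.std_distance
    return out


def write_rate_curve(curve: RateCurve, path) -> None:
    with open(path, "w") as fh:
        fh.write("kind\tcount\tA\tB\n")
        for c, (a, b) in sorted(curve.insertion.items()):
            fh.write(f"insertion\t{c}\t{a:.4f}\t{b:.4f}\n")
        for c, (a, b) in sorted(curve.deletion.items()):
            fh.write(f"deletion\t{c}\t{a:.4f}\t{b:.4f}\n")


def read_rate_curve(path) -> RateCurve:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    ins = {
        int(r["count"]): (float(r["A"]), float(r["B"]))
        for _, r in df[df["kind"] == "insertion"].iterrows()
    }
    dels = {
        int(r["count"]): (float(r["A"]), float(r["B"]))
        for _, r in df[df["kind"] == "deletion"].iterrows()
    }
    return RateCurve(insertion=ins, deletion=dels)


# ---------------------------------------------------------------------------
# simulation configs


def _length_model_from_dict(d: dict, gold_length: int) -> LengthModel:
    kind = d["kind"]
    if kind == "empirical":
        vals = np.sort(np.asarray(d["lsf_values"], dtype=float))
        return LengthModel(kind="empirical", gold_length=gold_length, lsf_values=vals)
    return LengthModel(
        kind=kind,
        gold_length=gold_length,
        mu=float(d["mu"]),
        sigma=float(d["sigma"]),
        shape=float(d.get("k", 0.0)),
    )


def read_sim_config(path, gold_length: int) -> SimConfig:
    """Load a simulation config from JSON or YAML.

    Recognized keys: model_kind, n_squiggles, seed, i0/i1/d0/d1,
    snr_target ("inf" or number), local_ref_lsf, length_model
    (kind/mu/sigma/k or kind=empirical/lsf_values), rate_curve
    ("reference" or a path to a rate-curve TSV), tail (b4/decay).
    """
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    snr = raw.get("snr_target", "inf")
    snr = math.inf if snr in ("inf", None) else float(snr)
    length_model = None
    if "length_model" in raw:
        length_model = _length_model_from_dict(raw["length_model"], gold_length)
    rate_curve = None
    if "rate_curve" in raw:
        rc = raw["rate_curve"]
        rate_curve = REFERENCE_RATE_CURVE if rc == "reference" else read_rate_curve(rc)
    tail = None
    if "tail" in raw:
        tail = (
            REFERENCE_TAIL
            if raw["tail"] == "reference"
            else TailModel(b4=float(raw["tail"].get("b4", 6.2)),
                           decay=float(raw["tail"].get("decay", 1.3)))
        )
    return SimConfig(
        model_kind=raw["model_kind"],
        n_squiggles=int(raw["n_squiggles"]),
        seed=int(raw["seed"]),
        i0=float(raw.get("i0", 0.0)),
        i1=float(raw.get("i1", 0.0)),
        d0=float(raw.get("d0", 0.0)),
        d1=float(raw.get("d1", 0.0)),
        rate_curve=rate_curve,
        tail=tail,
        length_model=length_model,
        local_ref_lsf=float(raw.get("local_ref_lsf", 1.7)),
        snr_target=snr,
    )


def write_json(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
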