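"""Tiling and half-hairpin probe design for barcode microarrays.

Each shRNA expression construct carries a unique 60-nt DNA barcode. The
array represents every barcode by six overlapping 25-nt probes stepping
across the barcode in 7-nt jumps (TP1..TP6), synthesized in triplicate per
subarray, so one barcode maps to 18 features per subarray. Probes are
stored as reverse complements of the barcode top strand so that hybridized
barcode fragments match them directly. The 21-nt half-hairpin stem of the
shRNA can serve as an alternative (single-probe) tag, optionally extended
by 4 nt of the common mir-30 vector context to 25 nt.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd
from Bio.Seq import Seq

logger = logging.getLogger("tilecode")

DNA_ALPHABET = frozenset("ACGT")

#: canonical design geometry: 25-nt probes, 7-nt step across a 60-nt barcode
BARCODE_LEN = 60
PROBE_LEN = 25
TILING_STEP = 7
STEM_LEN = 21

#: probe kinds
TILING = "tiling"
HALF_HAIRPIN_21 = "half_hairpin_21"
HALF_HAIRPIN_25 = "half_hairpin_25"
NEG_TILING = "negative_control_tiling"
NEG_HH = "negative_control_hh"

_HH_KINDS = frozenset({HALF_HAIRPIN_21, HALF_HAIRPIN_25, NEG_HH})


def _validate_dna(seq: str, what: str) -> str:
    seq = seq.strip().upper()
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(
            f"{what} contains non-ACGT character(s): {sorted(bad)!r}"
        )
    return seq


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class ConstructRecord:
    """One shRNA expression construct: barcode tag plus half-hairpin stem.

    ``hairpin_stem`` may be empty when a manifest carries barcodes only
    (e.g. FASTA input); such constructs get no half-hairpin probes.
    """

    construct_id: str
    barcode_seq: str
    hairpin_stem: str = ""
    gene_symbol: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "barcode_seq", _validate_dna(self.barcode_seq, f"barcode of {self.construct_id}")
        )
        if self.hairpin_stem:
            object.__setattr__(
                self, "hairpin_stem", _validate_dna(self.hairpin_stem, f"stem of {self.construct_id}")
            )
        if len(self.barcode_seq) != BARCODE_LEN:
            warnings.warn(
                f"barcode of {self.construct_id} is {len(self.barcode_seq)} nt "
                f"(expected {BARCODE_LEN}); tiling will emit a non-standard probe count",
                stacklevel=2,
            )
        if self.hairpin_stem and len(self.hairpin_stem) != STEM_LEN:
            warnings.warn(
                f"stem of {self.construct_id} is {len(self.hairpin_stem)} nt (expected {STEM_LEN})",
                stacklevel=2,
            )


@dataclass(frozen=True)
class Probe:
    """One array feature.

    ``offset`` is the 0-based start of the tiled window within the barcode
    (half-open coordinates); -1 for non-tiling probes. ``replicate`` indexes
    the synthesis replicate of the same sequence within a subarray.
    """

    probe_id: str
    construct_id: str
    kind: str
    offset: int
    length: int
    sequence: str
    replicate: int = 1
    subarray: int = 1

    def __post_init__(self) -> None:
        if self.length != len(self.sequence):
            raise ValueError(
                f"probe {self.probe_id}: declared length {self.length} != "
                f"sequence length {len(self.sequence)}"
            )
        if self.kind in (TILING, NEG_TILING) and self.offset < 0:
            raise ValueError(f"tiling probe {self.probe_id} needs a non-negative offset")

    @property
    def position_label(self) -> str:
        """TP1..TPn for tiling probes, HH for half-hairpin probes."""
        if self.kind in _HH_KINDS:
            return "HH"
        return f"TP{self.offset // TILING_STEP + 1}"


def tile_barcode(
    barcode: str,
    probe_len: int = PROBE_LEN,
    step: int = TILING_STEP,
    construct_id: str = "",
) -> list[Probe]:
    """Tile a barcode into overlapping probes complementary to it.

    Windows start at offsets 0, step, 2*step, ... as long as they fit; the
    default geometry (60-nt barcode, 25-nt probes, 7-nt step) yields six
    probes TP1..TP6 whose union covers the barcode exactly.
    """
    barcode = _validate_dna(barcode, "barcode")
    if step < 1:
        raise ValueError("step must be >= 1")
    if probe_len < 1:
        raise ValueError("probe_len must be >= 1")
    if len(barcode) < probe_len:
        raise ValueError(
            f"barcode too short: {len(barcode)} nt < probe length {probe_len} nt"
        )
    probes = []
    for k, offset in enumerate(range(0, len(barcode) - probe_len + 1, step)):
        window = barcode[offset : offset + probe_len]
        probes.append(
            Probe(
                probe_id=f"{construct_id}:TP{k + 1}" if construct_id else f"TP{k + 1}",
                construct_id=construct_id,
                kind=TILING,
                offset=offset,
                length=probe_len,
                sequence=reverse_complement(window),
            )
        )
    return probes


def half_hairpin_probe(
    stem: str,
    mir30_flank: str = "",
    extended: bool = False,
    construct_id: str = "",
) -> Probe:
    """Build the half-hairpin probe for a 21-nt stem.

    ``extended=True`` appends the reverse complement of the first 4 nt of
    the common mir-30 flank at the probe 3' end, giving a 25-nt probe with
    hybridization length comparable to the tiling probes.
    """
    stem = _validate_dna(stem, "stem")
    if len(stem) != STEM_LEN:
        raise ValueError(f"stem must be {STEM_LEN} nt, got {len(stem)}")
    seq = reverse_complement(stem)
    kind = HALF_HAIRPIN_21
    if extended:
        flank = _validate_dna(mir30_flank, "mir30 flank")
        if len(flank) < 4:
            raise ValueError("extended probe requires a mir-30 flank of >= 4 nt")
        seq = seq + reverse_complement(flank[:4])
        kind = HALF_HAIRPIN_25
    return Probe(
        probe_id=f"{construct_id}:HH" if construct_id else "HH",
        construct_id=construct_id,
        kind=kind,
        offset=-1,
        length=len(seq),
        sequence=seq,
    )


def probe_pair_overlap(offset_a: int, offset_b: int, probe_len: int = PROBE_LEN) -> int:
    """Shared nucleotides between two tiling windows of equal length.

    Adjacent probes in the default design (|offset difference| = 7) share
    18 of 25 nt; the full series by offset distance is 18/11/4/0/0.
    """
    if probe_len < 0:
        raise ValueError("probe_len must be non-negative")
    if offset_a < 0 or offset_b < 0:
        raise ValueError("offsets must be non-negative")
    return max(0, probe_len - abs(offset_a - offset_b))


@dataclass
class ArrayLayout:
    """The replicated probe content of one chip.

    The chip is divided into ``n_subarrays`` individually hybridizable
    subarrays of identical probe content; each probe sequence appears as
    ``replicate`` features per subarray.
    """

    probes: list[Probe]
    n_subarrays: int
    tiling_reps: int
    hh_reps: int
    negative_construct_ids: frozenset = frozenset()
    _frame: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    def frame(self) -> pd.DataFrame:
        """All features as a DataFrame indexed by probe_id."""
        if self._frame is None:
            cols = ["probe_id", "construct_id", "kind", "offset", "length",
                    "sequence", "replicate", "subarray"]
            df = pd.DataFrame([{c: getattr(p, c) for c in cols} for p in self.probes],
                              columns=cols)
            df["position"] = [p.position_label for p in self.probes]
            self._frame = df.set_index("probe_id")
        return self._frame

    def sample_features(self, subarray: int = 1) -> pd.DataFrame:
        """Features of one subarray — the probe set a single sample sees."""
        df = self.frame()
        return df[df["subarray"] == subarray]

    def negative_probe_ids(self, subarray: int = 1) -> list[str]:
        df = self.sample_features(subarray)
        return list(df.index[df["construct_id"].isin(self.negative_construct_ids)])

    def __len__(self) -> int:
        return len(self.probes)


def build_array_layout(
    constructs: Sequence[ConstructRecord],
    negatives: Sequence[ConstructRecord] = (),
    tiling_reps: int = 3,
    hh_reps: int = 4,
    n_subarrays: int = 8,
    probe_len: int = PROBE_LEN,
    step: int = TILING_STEP,
    mir30_flank: str = "",
    neg_reps: int = 3,
) -> ArrayLayout:
    """Assemble the full replicated layout from construct manifests.

    Per subarray every construct contributes its tiling probes in
    ``tiling_reps`` replicate features, plus (when a stem is present) one
    half-hairpin probe in ``hh_reps`` replicates. Negative-control
    constructs — barcodes absent from every hybridized pool — contribute
    their tiling probes and one half-hairpin probe each in ``neg_reps``
    replicates; their features are used for background estimation.
    """
    ids = [c.construct_id for c in constructs] + [n.construct_id for n in negatives]
    dup = {i for i in ids if ids.count(i) > 1}
    if dup:
        raise ValueError(f"duplicate construct_id(s): {sorted(dup)}")

    probes: list[Probe] = []

    def emit(rec: ConstructRecord, negative: bool) -> None:
        t_kind = NEG_TILING if negative else TILING
        t_reps = neg_reps if negative else tiling_reps
        h_kind = NEG_HH if negative else (HALF_HAIRPIN_25 if mir30_flank else HALF_HAIRPIN_21)
        h_reps = neg_reps if negative else hh_reps
        templates = tile_barcode(rec.barcode_seq, probe_len, step, rec.construct_id)
        hh = None
        if rec.hairpin_stem:
            hh = half_hairpin_probe(
                rec.hairpin_stem, mir30_flank, extended=bool(mir30_flank),
                construct_id=rec.construct_id,
            )
        for sub in range(1, n_subarrays + 1):
            for tp in templates:
                for r in range(1, t_reps + 1):
                    probes.append(Probe(
                        probe_id=f"{tp.probe_id}:r{r}:s{sub}",
                        construct_id=rec.construct_id,
                        kind=t_kind,
                        offset=tp.offset,
                        length=tp.length,
                        sequence=tp.sequence,
                        replicate=r,
                        subarray=sub,
                    ))
            if hh is not None:
                for r in range(1, h_reps + 1):
                    probes.append(Probe(
                        probe_id=f"{hh.probe_id}:r{r}:s{sub}",
                        construct_id=rec.construct_id,
                        kind=h_kind,
                        offset=-1,
                        length=hh.length,
                        sequence=hh.sequence,
                        replicate=r,
                        subarray=sub,
                    ))

    for rec in constructs:
        emit(rec, negative=False)
    for rec in negatives:
        emit(rec, negative=True)

    layout = ArrayLayout(
        probes=probes,
        n_subarrays=n_subarrays,
        tiling_reps=tiling_reps,
        hh_reps=hh_reps,
        negative_construct_ids=frozenset(n.construct_id for n in negatives),
    )
    logger.info(
        "layout: %d constructs + %d negatives -> %d features (%d subarrays)",
        len(constructs), len(negatives), len(probes), n_subarrays,
    )
    return layout
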