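"""I/O, coordinate conventions, and the queryable containers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from svpath.genomic_io import (
    ChromSizes,
    GenomicIntervalSet,
    ParseError,
    SignalTrack,
    SVRecord,
    filter_svs,
    read_score_table,
    read_sv_bed,
    read_sv_vcf,
    write_score_table,
)


# ---------------------------------------------------------------------------
# SVRecord / ChromSizes
# ---------------------------------------------------------------------------

def test_svrecord_invariants():
    sv = SVRecord("chr1", 100, 600, "DEL", 1, id="x")
    assert sv.length == 500
    with pytest.raises(ValueError):
        SVRecord("chr1", 100, 100, "DEL", 1)
    with pytest.raises(ValueError):
        SVRecord("chr1", 0, 10, "INV", 1)
    with pytest.raises(ValueError):
        SVRecord("chr1", 0, 10, "DEL", 2)
    with pytest.raises(ValueError):
        SVRecord("chr1", 0, 10, "DEL", 1, allele_freq=1.5)


def test_chrom_sizes_roundtrip_and_checks(tmp_path):
    sizes = ChromSizes({"chr1": 1000, "chr2": 500})
    path = tmp_path / "genome.sizes"
    sizes.to_file(path)
    back = ChromSizes.from_file(path)
    assert dict(back) == dict(sizes)
    with pytest.raises(ValueError):
        ChromSizes({"chr1": 0})
    sizes.check_svs([SVRecord("chr1", 0, 1000, "DEL", 1, id="ok")])
    with pytest.raises(ValueError, match="unknown chromosome"):
        sizes.check_svs([SVRecord("chr9", 0, 10, "DEL", 1, id="bad")])
    with pytest.raises(ValueError, match="exceeds"):
        sizes.check_svs([SVRecord("chr2", 0, 501, "DEL", 1, id="bad")])


# ---------------------------------------------------------------------------
# BED SV reader + cohort filters
# ---------------------------------------------------------------------------

def test_read_sv_bed_maps_fields(tmp_path):
    path = tmp_path / "svs.bed"
    path.write_text("chr1\t100\t600\tDEL\nchr1\t700\t900\tDUP\nchr2\t10\t80\tDEL\n")
    svs = read_sv_bed(path, label=1)
    assert [sv.interval() for sv in svs] == [
        ("chr1", 100, 600),
        ("chr1", 700, 900),
        ("chr2", 10, 80),
    ]
    assert svs[0].length == 500 and svs[0].label == 1 and svs[1].sv_type == "DUP"
    assert len({sv.id for sv in svs}) == 3


@pytest.mark.parametrize(
    "line, match",
    [
        ("chr1\t100\t100\tDEL", "line 1"),
        ("chr1\tx\t200\tDEL", "line 1"),
        ("chr1\t100", "line 1"),
        ("chr1\t100\t200\tINV", "line 1"),
    ],
)
def test_read_sv_bed_parse_errors_name_line(tmp_path, line, match):
    path = tmp_path / "bad.bed"
    path.write_text(line + "\n")
    with pytest.raises(ParseError, match=match):
        read_sv_bed(path, label=0)


VCF_TEXT = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=100000>
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">
##INFO=<ID=END,Number=1,Type=Integer,Description="End">
##INFO=<ID=AF,Number=A,Type=Float,Description="AF">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
chr1\t101\tdel1\tN\t<DEL>\t.\t.\tSVTYPE=DEL;END=600;AF=0.01
chr1\t1001\tdel2\tN\t<DEL>\t.\t.\tSVTYPE=DEL;END=1600
chr1\t2001\tdup1\tN\t<DUP>\t.\t.\tSVTYPE=DUP;END=2600
chr1\t3001\tinv1\tN\t<INV>\t.\t.\tSVTYPE=INV;END=3600
chr1\t4001\tbnd1\tN\tN[chr2:5[\t.\t.\tSVTYPE=BND
chr1\t5001\tdel3\tN\t<DEL>\t.\t.\tSVTYPE=DEL
"""


def test_read_sv_vcf_conversion_and_type_filter(tmp_path):
    path = tmp_path / "svs.vcf"
    path.write_text(VCF_TEXT)
    with pytest.warns(UserWarning, match="no usable END"):
        svs = read_sv_vcf(path, label=0)
    # 2 DEL + 1 DUP kept; INV, BND, END-less DEL dropped
    assert len(svs) == 3
    assert svs[0].start == 100 and svs[0].end == 600  # POS=101 -> 0-based 100
    assert svs[0].allele_freq == pytest.approx(0.01)
    assert {sv.sv_type for sv in svs} == {"DEL", "DUP"}


def _sv(length, sv_type="DEL", af=None, label=0, i=0):
    return SVRecord("chr1", 0, length, sv_type, label, allele_freq=af, id=f"s{i}")


def test_filter_svs_length_type_af_bounds():
    svs = [
        _sv(50, i=0),  # boundary: excluded (strict >)
        _sv(51, i=1),
        _sv(200, "DUP", i=2),
        _sv(300, af=0.004, i=3),
        _sv(300, af=0.006, i=4),
        _sv(300, af=None, i=5),
    ]
    out = filter_svs(svs, min_length=50, sv_type="DEL", min_af=0.005)
    assert [sv.id for sv in out] == ["s1", "s4", "s5"]
    # idempotent subset
    assert filter_svs(out, min_length=50, sv_type="DEL", min_af=0.005) == out
    assert set(out) <= set(svs)
    with pytest.raises(ValueError):
        filter_svs(svs, min_af=0.5, max_af=0.1)


# ---------------------------------------------------------------------------
# Score table round trip
# ---------------------------------------------------------------------------

def test_score_table_roundtrip(tmp_path):
    import pandas as pd

    table = pd.DataFrame(
        {
            "id": ["a", "b"],
            "chrom": ["chr1", "chr2"],
            "start": [0, 10],
            "end": [100, 60],
            "sv_type": ["DEL", "DUP"],
            "label": [1, 0],
            "score": [0.123456789012345, 1 / 3],
            "group": ["intermediate", "benign"],
        }
    )
    path = tmp_path / "scores.tsv"
    write_score_table(table, path)
    lines = path.read_text().splitlines()
    assert len(lines) == 3  # header + 2 rows
    back = read_score_table(path)
    assert list(back["score"]) == list(table["score"])  # exact float round trip
    write_score_table(table.iloc[:0], path)
    assert len(path.read_text().splitlines()) == 1  # header-only for empty table


# ---------------------------------------------------------------------------
# GenomicIntervalSet
# ---------------------------------------------------------------------------

def test_interval_set_merges_and_counts():
    iset = GenomicIntervalSet(
        [("chr1", 10, 20), ("chr1", 15, 30), ("chr1", 40, 50), ("chr2", 0, 5)]
    )
    assert iset.merged_intervals("chr1").tolist() == [[10, 30], [40, 50]]
    assert int(iset.overlap_bases("chr1", 0, 100)) == 30
    assert int(iset.overlap_bases("chr1", 25, 45)) == 10
    assert int(iset.overlap_bases("chrZ", 0, 100)) == 0  # absent chromosome -> 0


def test_interval_set_overlap_matches_bruteforce():
    rng = np.random.default_rng(42)
    for _ in range(200):
        n = int(rng.integers(1, 15))
        starts = rng.integers(0, 500, size=n)
        ends = starts + rng.integers(1, 80, size=n)
        iset = GenomicIntervalSet([("c", int(s), int(e)) for s, e in zip(starts, ends)])
        covered = np.zeros(1000, dtype=bool)
        for s, e in zip(starts, ends):
            covered[s:e] = True
        a = int(rng.integers(0, 900))
        b = a + int(rng.integers(1, 100))
        assert int(iset.overlap_bases("c", a, b)) == int(covered[a:b].sum())


# ---------------------------------------------------------------------------
# SignalTrack
# ---------------------------------------------------------------------------

def test_track_values_window_length_and_content():
    track = SignalTrack(
        "t", {"c": (np.array([0, 10, 25, 40]), np.array([1.0, 2.0, 0.5]))}
    )
    vals = track.values("c", 5, 30)
    assert len(vals) == 25
    assert vals[0] == 1.0 and vals[10] == 2.0 and vals[-1] == 0.5
    assert track.range_sum("c", 5, 30) == pytest.approx(vals.sum())
    with pytest.raises(ValueError):
        track.values("c", 5, 45)  # beyond chromosome end


@settings(max_examples=60, derandomize=True)
@given(
    data=st.lists(st.floats(-5, 5), min_size=1, max_size=12),
    cuts=st.tuples(st.integers(0, 120), st.integers(0, 120), st.integers(0, 120)),
)
def test_track_adjacent_windows_sum_to_union(data, cuts):
    """sum over [a,m) + sum over [m,b) == sum over [a,b) for any split."""
    bounds = np.arange(0, 10 * (len(data) + 1), 10)
    track = SignalTrack("t", {"c": (bounds, np.array(data))})
    L = int(bounds[-1])
    a, m, b = sorted(int(c) % (L + 1) for c in cuts)
    left = track.range_sum("c", a, m)
    right = track.range_sum("c", m, b)
    assert left + right == pytest.approx(track.range_sum("c", a, b), abs=1e-9)


def test_bedgraph_roundtrip_fills_gaps(tmp_path):
    sizes = ChromSizes({"c1": 100, "c2": 50})
    path = tmp_path / "sig.bedGraph"
    path.write_text("c1\t10\t20\t2.5\nc1\t30\t60\t-1.0\n")
    track = SignalTrack.from_bedgraph(path, sizes, name="sig")
    assert track.range_sum("c1", 0, 100) == pytest.approx(2.5 * 10 - 1.0 * 30)
    assert track.range_sum("c1", 0, 10) == 0.0  # gap filled with zeros
    assert track.range_sum("c2", 0, 50) == 0.0  # absent chromosome all-zero
    out = tmp_path / "back.bedGraph"
    track.to_bedgraph(out)
    back = SignalTrack.from_bedgraph(out, sizes, name="sig")
    pos = np.arange(0, 101, 7)
    assert np.allclose(back.prefix("c1", pos), track.prefix("c1", pos))


def test_track_representation_independence():
    """Splitting a segment into equal-valued halves changes nothing."""
    t1 = SignalTrack("t", {"c": (np.array([0, 20, 40]), np.array([3.0, 1.0]))})
    t2 = SignalTrack(
        "t", {"c": (np.array([0, 10, 20, 40]), np.array([3.0, 3.0, 1.0]))}
    )
    pos = np.arange(41)
    assert np.allclose(t1.prefix("c", pos), t2.prefix("c", pos))
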