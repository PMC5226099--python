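import hashlib

import numpy as np
import pytest

from enhancerstack.features import kmer_frequencies, label_windows, map_signal
from enhancerstack.genomic_io import read_bed, read_broadpeak
from enhancerstack.synthetic_data import (
    MarkSpec,
    SynthSpec,
    generate_sequences,
    generate_tissue,
    simulate_study,
    tissue_labels,
)


def small_spec(seed=0, **kwargs):
    defaults = dict(
        chrom_sizes={"chrA": 200_000, "chrB": 100_000},
        marks=[MarkSpec("mk1", effect=3.0, noise_sd=0.25), MarkSpec("mk0", effect=0.0)],
        n_tissues=2,
        seed=seed,
    )
    defaults.update(kwargs)
    return SynthSpec(**defaults)


def _dir_hashes(paths):
    return {p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in paths}


class TestGenerateTissue:
    def test_fixed_seed_gives_byte_identical_files(self, tmp_path):
        spec = small_spec(seed=5)
        a = generate_tissue(spec, 0, tmp_path / "a")
        b = generate_tissue(spec, 0, tmp_path / "b")
        files_a = [*a.peak_paths.values(), a.label_path, a.truth_path]
        files_b = [*b.peak_paths.values(), b.label_path, b.truth_path]
        assert _dir_hashes(files_a) == _dir_hashes(files_b)

    def test_enhancer_fraction_exact_on_large_genome(self):
        # 10-Mb genome -> 50,000 windows -> exactly 1000 positives at 2%
        spec = small_spec(chrom_sizes={"chrA": 10_000_000})
        labels = tissue_labels(spec, 0)
        assert len(labels) == 50_000
        assert labels.sum() == 1000

    def test_informative_mark_enriched_at_positives(self, tmp_path):
        spec = small_spec(seed=1)
        tf = generate_tissue(spec, 0, tmp_path)
        grid = spec.grid()
        fm = map_signal({"mk1": read_broadpeak(tf.peak_paths["mk1"])}, grid)
        sig = fm.values[:, 0]
        pos, neg = sig[tf.labels == 1], sig[tf.labels == 0]
        se = pos.std(ddof=1) / np.sqrt(len(pos))
        # positives carry the configured lift over the (mostly empty) negatives
        assert pos.mean() - neg.mean() > 3.0 - 3 * se

    def test_uninformative_mark_carries_no_label_signal(self, tmp_path):
        spec = small_spec(seed=2)
        tf = generate_tissue(spec, 0, tmp_path)
        grid = spec.grid()
        fm = map_signal({"mk0": read_broadpeak(tf.peak_paths["mk0"])}, grid)
        sig = fm.values[:, 0]
        pos, neg = sig[tf.labels == 1], sig[tf.labels == 0]
        # background coverage only: means agree within Monte-Carlo noise
        assert abs(pos.mean() - neg.mean()) < 5 * neg.std(ddof=1) / np.sqrt(len(pos))

    def test_emitted_files_reread_losslessly(self, tmp_path):
        spec = small_spec(seed=3)
        tf = generate_tissue(spec, 0, tmp_path)
        grid = spec.grid()
        for path in tf.peak_paths.values():
            records = read_broadpeak(path)
            assert records and all(r.signal_value > 0 for r in records)
        # label BED recovers the truth labels through the labeling rule
        relabeled = label_windows(grid, read_bed(tf.label_path))
        np.testing.assert_array_equal(relabeled, tf.labels)

    def test_shared_pool_is_common_across_tissues(self):
        spec = small_spec(shared_enhancer_fraction=1.0)
        np.testing.assert_array_equal(tissue_labels(spec, 0), tissue_labels(spec, 1))
        spec2 = small_spec(shared_enhancer_fraction=0.0)
        both = (tissue_labels(spec2, 0) == 1) & (tissue_labels(spec2, 1) == 1)
        assert both.sum() < 0.2 * tissue_labels(spec2, 0).sum()  # mostly disjoint

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            small_spec(enhancer_fraction=1.5)
        with pytest.raises(ValueError):
            small_spec(shared_enhancer_fraction=-0.1)


@pytest.fixture(scope="module")
def study(tmp_path_factory):
    spec = small_spec(seed=4, chrom_sizes={"chrA": 60_000, "chrB": 30_000})
    out = tmp_path_factory.mktemp("seqstudy")
    return spec, simulate_study(spec, out, with_sequence=True)


class TestGenerateSequences:
    def test_fasta_deterministic(self, study, tmp_path):
        spec, files = study
        union = np.zeros(spec.grid().n_windows, dtype=int)
        for tf in files.tissues:
            union |= tf.labels
        again = generate_sequences(spec, union, tmp_path / "again.fa")
        assert again.read_bytes() == files.fasta_path.read_bytes()

    def test_sequence_lengths_match_chrom_sizes(self, study):
        spec, files = study
        from pyfaidx import Fasta

        fasta = Fasta(str(files.fasta_path))
        for chrom, size in spec.chrom_sizes.items():
            assert len(fasta[chrom]) == size

    def test_motif_enriched_in_enhancer_windows(self, study):
        spec, files = study
        from pyfaidx import Fasta

        fasta = Fasta(str(files.fasta_path))
        grid = spec.grid()
        union = np.zeros(grid.n_windows, dtype=int)
        for tf in files.tissues:
            union |= tf.labels

        def motif_freq(window):
            seq = str(fasta[window.chrom][window.start : window.end])
            # naive sliding-window count oracle
            count = sum(seq[i : i + 4] == "GTCA" for i in range(len(seq) - 3))
            return count / (len(seq) - 3)

        pos_freq = np.mean([motif_freq(grid.windows[i]) for i in np.flatnonzero(union == 1)])
        neg_idx = np.flatnonzero(union == 0)[:200]
        neg_freq = np.mean([motif_freq(grid.windows[i]) for i in neg_idx])
        assert pos_freq > 3 * neg_freq

    def test_kmer_features_pick_up_the_motif(self, study):
        spec, files = study
        from pyfaidx import Fasta

        fasta = Fasta(str(files.fasta_path))
        grid = spec.grid()
        tf = files.tissues[0]
        pos_w = grid.windows[int(np.flatnonzero(tf.labels == 1)[0])]
        neg_w = grid.windows[int(np.flatnonzero(tf.labels == 0)[0])]
        names_offset = 4 + 16 + 64  # tetramer block starts here
        import itertools

        tetramers = ["".join(p) for p in itertools.product("ACGT", repeat=4)]
        gtca = names_offset + tetramers.index("GTCA")
        f_pos = kmer_frequencies(str(fasta[pos_w.chrom][pos_w.start : pos_w.end]))
        f_neg = kmer_frequencies(str(fasta[neg_w.chrom][neg_w.start : neg_w.end]))
        assert f_pos[gtca] > f_neg[gtca]


class TestSimulateStudy:
    def test_study_layout_and_truth_table(self, tmp_path):
        spec = small_spec(seed=6)
        files = simulate_study(spec, tmp_path)
        assert files.chrom_sizes_path.exists()
        assert len(files.tissues) == 2
        header, *rows = files.truth_path.read_text().splitlines()
        assert header == "window\ttissue\tlabel"
        assert len(rows) == 2 * spec.grid().n_windows
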