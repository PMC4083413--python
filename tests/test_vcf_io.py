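"""VCF/INI parsing and the aggregated-VCF dialect round trip + validator."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import snvblur as sb
from snvblur.model import FormatError, ValidationError

from conftest import CONTACT, make_meta

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
)


def write_vcf(tmp_path, body, header=VCF_HEADER, name="x.vcf"):
    path = tmp_path / name
    path.write_text(header + body)
    return str(path)


class TestReadVcf:
    def test_header_only_gives_one_sample_no_calls(self, tmp_path):
        ds = sb.read_vcf(write_vcf(tmp_path, ""))
        assert ds.sample_ids == ["S1"]
        assert ds.calls == {}

    def test_het_hom_and_homref_genotypes(self, tmp_path):
        body = (
            "chr1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/1\n"
            "chr1\t200\t.\tC\tT\t.\tPASS\t.\tGT\t1/1\n"
            "chr1\t300\t.\tG\tA\t.\tPASS\t.\tGT\t0/0\n"
        )
        ds = sb.read_vcf(write_vcf(tmp_path, body))
        assert ds.calls == {
            sb.SnvKey("chr1", 100, "A", "G"): {"S1": "het"},
            sb.SnvKey("chr1", 200, "C", "T"): {"S1": "hom_alt"},
        }
        assert ds.rsids == {sb.SnvKey("chr1", 100, "A", "G"): "rs1"}

    def test_indel_skipped_and_counted(self, tmp_path):
        ds = sb.read_vcf(write_vcf(tmp_path, "chr1\t100\t.\tAT\tA\t.\tPASS\t.\tGT\t0/1\n"))
        assert ds.calls == {}
        assert ds.skip_stats.indels == 1

    def test_multiallelic_split_per_alt(self, tmp_path):
        body = "chr1\t100\t.\tA\tG,C\t.\tPASS\t.\tGT\t1/2\n"
        ds = sb.read_vcf(write_vcf(tmp_path, body))
        assert ds.calls == {
            sb.SnvKey("chr1", 100, "A", "G"): {"S1": "het"},
            sb.SnvKey("chr1", 100, "A", "C"): {"S1": "het"},
        }

    def test_phased_treated_as_unphased(self, tmp_path):
        ds = sb.read_vcf(write_vcf(tmp_path, "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t1|1\n"))
        assert list(ds.calls.values()) == [{"S1": "hom_alt"}]

    def test_missing_chrom_header_is_format_error(self, tmp_path):
        path = tmp_path / "bad.vcf"
        path.write_text("##fileformat=VCFv4.2\n")
        with pytest.raises(FormatError):
            sb.read_vcf(str(path))

    def test_sample_id_override(self, tmp_path):
        ds = sb.read_vcf(
            write_vcf(tmp_path, "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\n"),
            sample_id_override="patient_7",
        )
        assert ds.sample_ids == ["patient_7"]
        assert list(ds.calls.values()) == [{"patient_7": "het"}]


class TestIni:
    def test_minimal_mandatory_set(self, tmp_path):
        path = tmp_path / "m.ini"
        path.write_text(
            "[global]\ntrait = epilepsy\ncontact_name = A\n"
            "contact_affiliation = B\ncontact_email = a@b.c\n"
            "[sample:s1]\nstatus = patient\n[sample:s2]\nstatus = control\n"
        )
        samples = sb.read_ini(str(path))
        assert [s.sample_id for s in samples] == ["s1", "s2"]
        assert samples[0].gender is None and samples[0].platform is None
        assert samples[1].status == "control"

    def test_missing_trait_is_validation_error(self, tmp_path):
        path = tmp_path / "m.ini"
        path.write_text(
            "[global]\ncontact_name = A\ncontact_affiliation = B\n"
            "contact_email = a@b.c\n[sample:s1]\nstatus = patient\n"
        )
        with pytest.raises(ValidationError, match="trait"):
            sb.read_ini(str(path))

    def test_malformed_hpo_id_names_the_id(self, tmp_path):
        path = tmp_path / "m.ini"
        path.write_text(
            "[global]\ntrait = t\ncontact_name = A\ncontact_affiliation = B\n"
            "contact_email = a@b.c\n[sample:s1]\nstatus = patient\n"
            "hpo_present = HP:123\n"
        )
        with pytest.raises(ValidationError, match="HP:123"):
            sb.read_ini(str(path))

    def test_full_round_trip(self, tmp_path):
        samples = [
            make_meta(
                "s1",
                hpo_present=frozenset(["HP:0001250", "HP:0001263"]),
                hpo_absent=frozenset(["HP:0000556"]),
                gender="female",
                platform="HiSeq",
                enrichment="SureSelect",
                pi="PI X",
                contact_release=True,
                vcf="s1.vcf",
            ),
            make_meta("s2", trait="ibd", status="control"),
        ]
        path = tmp_path / "rt.ini"
        sb.write_ini(samples, str(path))
        assert sb.read_ini(str(path)) == samples

    @settings(max_examples=25, deadline=None)
    @given(st.data())
    def test_property_round_trip(self, data):
        hpo = st.sets(
            st.integers(0, 9999999).map(lambda n: f"HP:{n:07d}"), max_size=3
        )
        present = data.draw(hpo)
        absent = data.draw(hpo.map(lambda s: s - present))
        sample = make_meta(
            data.draw(st.from_regex(r"[A-Za-z][A-Za-z0-9_-]{0,10}", fullmatch=True)),
            trait=data.draw(st.text(st.characters(categories=("L", "N"), include_characters=" "), min_size=1, max_size=20).map(str.strip).filter(bool)),
            status=data.draw(st.sampled_from(["patient", "control"])),
            hpo_present=frozenset(present),
            hpo_absent=frozenset(absent),
            gender=data.draw(st.sampled_from([None, "male", "female"])),
            platform=data.draw(st.sampled_from([None, "P1", "Platform 2"])),
            contact_release=data.draw(st.booleans()),
        )
        import tempfile
        from pathlib import Path

        with tempfile.TemporaryDirectory() as tmp:
            path = Path(tmp) / "p.ini"
            sb.write_ini([sample], str(path))
            assert sb.read_ini(str(path)) == [sample]


@pytest.fixture(scope="module")
def store_and_path(tmp_path_factory):
    ds = sb.simulate_cohort(sb.SfsConfig(n_samples=6, n_sites=150, seed=3))
    store, _, _ = sb.aggregate_dataset(
        ds, sb.AggregateConfig(seed=5, passphrase="pw")
    )
    path = tmp_path_factory.mktemp("agg") / "agg.vcf"
    sb.write_aggregated_vcf(store, str(path))
    return store, str(path)


class TestAggregatedDialect:
    def test_empty_store_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.vcf"
        sb.write_aggregated_vcf(sb.AggregatedStore(n_samples=0), str(path))
        lines = path.read_text().splitlines()
        assert all(l.startswith("#") for l in lines)
        assert any(l.startswith("##snvblur_dialect=") for l in lines)
        assert sb.read_aggregated_vcf(str(path)).records == []

    def test_round_trip_is_field_exact(self, store_and_path):
        store, path = store_and_path
        assert sb.read_aggregated_vcf(path) == store

    def test_blurred_lines_carry_no_subsample_tokens(self, store_and_path):
        store, path = store_and_path
        sub_ids = {sid for r in store.records for sid, _ in r.sub_calls}
        assert sub_ids, "fixture should have unblurred records"
        for line in open(path):
            if "GBBLUR=1" in line:
                assert "GBSUBS" not in line
                assert not any(sid in line for sid in sub_ids)

    def test_fresh_file_validates_clean(self, store_and_path):
        _, path = store_and_path
        report = sb.validate_aggregated_vcf(path)
        assert report.ok, str(report)

    def test_missing_dialect_line_is_format_error(self, tmp_path):
        path = tmp_path / "plain.vcf"
        path.write_text(VCF_HEADER)
        with pytest.raises(FormatError):
            sb.read_aggregated_vcf(str(path))

    @pytest.mark.parametrize(
        "mutate, expected_kind",
        [
            # blurred record that still names a sub-sample
            (lambda l: l.replace("GBBLUR=1;", "GBBLUR=1;GBSUBS=deadbeef|H;"), "blurred-with-linkage"),
            # carrier count inflated by one
            (None, "count-mismatch"),
        ],
    )
    def test_corruption_is_reported(self, store_and_path, tmp_path, mutate, expected_kind):
        _, path = store_and_path
        lines = open(path).read().splitlines()
        corrupted = []
        done = False
        for line in lines:
            if not done and not line.startswith("#"):
                if mutate is not None and "GBBLUR=1" in line:
                    line = mutate(line)
                    done = True
                elif mutate is None and "GBSUBS" in line:
                    import re

                    n = int(re.search(r"GBCAR=(\d+)", line).group(1))
                    line = line.replace(f"GBCAR={n}", f"GBCAR={n + 1}")
                    done = True
            corrupted.append(line)
        assert done
        bad = tmp_path / "bad.vcf"
        bad.write_text("\n".join(corrupted) + "\n")
        report = sb.validate_aggregated_vcf(str(bad))
        kinds = [v.kind for v in report.violations]
        assert expected_kind in kinds

    def test_duplicate_and_unsorted_detected(self, store_and_path, tmp_path):
        _, path = store_and_path
        lines = open(path).read().splitlines()
        data = [l for l in lines if not l.startswith("#")]
        header = [l for l in lines if l.startswith("#")]
        shuffled = header + [data[1], data[0], data[1]] + data[2:]
        bad = tmp_path / "dup.vcf"
        bad.write_text("\n".join(shuffled) + "\n")
        kinds = {v.kind for v in sb.validate_aggregated_vcf(str(bad)).violations}
        assert "duplicate-key" in kinds and "unsorted" in kinds
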