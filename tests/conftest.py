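import textwrap

import pytest

from cdeharvest import GeneratorConfig, NoiseModel, generate_studyset

MINI_ODM = textwrap.dedent("""\
    <?xml version="1.0" encoding="UTF-8"?>
    <ODM xmlns="http://www.cdisc.org/ns/odm/v1.3" ODMVersion="1.3"
         FileType="Snapshot" FileOID="mini">
      <Study OID="T-001">
        <GlobalVariables>
          <StudyName>T-001</StudyName>
          <StudyDescription>mini</StudyDescription>
          <ProtocolName>T-001</ProtocolName>
        </GlobalVariables>
        <MetaDataVersion OID="T-001.MDV" Name="metadata">
          <FormDef OID="F1" Name="Vital Signs" Repeating="No">
            <ItemGroupRef ItemGroupOID="F1.IG" Mandatory="No"/>
          </FormDef>
          <ItemGroupDef OID="F1.IG" Name="Vital Signs" Repeating="No">
            <ItemRef ItemOID="IT1" OrderNumber="1" Mandatory="No"/>
            <ItemRef ItemOID="IT2" OrderNumber="2" Mandatory="No"/>
          </ItemGroupDef>
          <ItemDef OID="IT1" Name="HR" DataType="integer" SDSVarName="VSHR">
            <Question><TranslatedText xml:lang="en">Heart Rate</TranslatedText></Question>
          </ItemDef>
          <ItemDef OID="IT2" Name="Weight label from name" DataType="float"/>
        </MetaDataVersion>
      </Study>
    </ODM>
""")


@pytest.fixture
def mini_odm(tmp_path):
    """One-form / two-item ODM file; item 1 has both Question and Name."""
    p = tmp_path / "mini.odm.xml"
    p.write_text(MINI_ODM)
    return p


def small_config(seed=7, noise=None):
    """A compact corpus (2 areas, ~30 forms) for fast unit tests."""
    return GeneratorConfig(
        n_trials_per_area={"oncology": 2, "cardiovascular": 2},
        forms_per_area={"oncology": 16, "cardiovascular": 14},
        elements_per_form=(4, 12),
        noise=noise if noise is not None else NoiseModel(),
        seed=seed,
    )


@pytest.fixture
def small_corpus():
    """Small noisy corpus plus its ground truth."""
    return generate_studyset(small_config(seed=7))


@pytest.fixture
def small_corpus_clean():
    """Same shape, zero label noise."""
    return generate_studyset(small_config(seed=7, noise=NoiseModel.zero()))


@pytest.fixture(scope="session")
def default_corpus():
    """The full default-shape corpus (23 trials, 1086 forms)."""
    return generate_studyset(GeneratorConfig(seed=1))
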