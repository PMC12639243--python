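import pytest

import nhaneskit as nk
from nhaneskit.metadata_model import CodebookEntry, QuestionnaireVariable


@pytest.fixture(scope="session")
def clean_fixture(tmp_path_factory):
    """One default synthetic snapshot tree, no injections."""
    out = tmp_path_factory.mktemp("clean_fx")
    return nk.make_snapshot(nk.default_spec(seed=7), out)


@pytest.fixture(scope="session")
def clean_store(clean_fixture):
    return nk.load_fixture_snapshot(clean_fixture)


@pytest.fixture(scope="session")
def smq_doc(clean_fixture):
    html = (clean_fixture.doc_dir / "SMQ.htm").read_text(encoding="utf-8")
    return nk.parse_doc_page(html, source_path="SMQ.htm")


def doc_from_shorthand(table_name, blocks):
    """Build a CodebookDoc from (variable, [(code, description, skip), ...])
    shorthand — the hand-construction route used all over the skip tests."""
    variables = []
    for name, rows in blocks:
        var = QuestionnaireVariable(variable=name, table_name=table_name,
                                    sas_label=name.title())
        entries = []
        for code, desc, skip in rows:
            entries.append(
                CodebookEntry(
                    variable=name, table_name=table_name,
                    code_or_value=str(code), value_description=desc,
                    skip_to_item=skip,
                )
            )
        variables.append((var, entries))
    return nk.CodebookDoc(table_name=table_name, variables=variables)


@pytest.fixture
def fig2_doc():
    """Smoking-style flow: a gate question whose No answer skips the
    age-started question."""
    return doc_from_shorthand(
        "SMOKE",
        [
            ("SMQ020", [("1", "Yes", None), ("2", "No", "SMD070"),
                        ("7", "Refused", "SMD070")]),
            ("SMD030", [("1", "Teen", None), ("2", "Adult", None)]),
            ("SMD070", [("1", "Every day", None), ("2", "Not at all", None)]),
        ],
    )
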