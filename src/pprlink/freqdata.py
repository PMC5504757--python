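"""Bundled synthetic value-frequency tables for the person-record generator.

The tables emulate the statistical shape of Australian population name and
address data — skewed value frequencies with a small number of very common
values and a long tail — without reproducing any real population file. Rank
weights follow a shifted power law, weight(rank) ∝ 1/(rank + offset), which
keeps the most common value's share near realistic population levels
(top surname share roughly 1–2%) instead of the much heavier head a pure
Zipf law would give.

All tables are plain ``value → probability`` dicts and can be replaced
wholesale through :class:`pprlink.synthetic.GeneratorConfig`.
"""

from __future__ import annotations

import numpy as np

FIRST_NAMES = [
    "JAMES", "JOHN", "ROBERT", "MICHAEL", "DAVID", "WILLIAM", "RICHARD",
    "THOMAS", "PETER", "CHRISTOPHER", "DANIEL", "MATTHEW", "ANDREW", "PAUL",
    "MARK", "GEORGE", "STEVEN", "KENNETH", "EDWARD", "BRIAN", "ANTHONY",
    "KEVIN", "JASON", "JEFFREY", "RYAN", "JACOB", "NICHOLAS", "GARY",
    "JONATHAN", "STEPHEN", "LARRY", "JUSTIN", "SCOTT", "BRANDON", "BENJAMIN",
    "SAMUEL", "GREGORY", "ALEXANDER", "PATRICK", "FRANK", "RAYMOND", "JACK",
    "DENNIS", "JERRY", "TYLER", "AARON", "JOSE", "ADAM", "NATHAN", "HENRY",
    "MARY", "PATRICIA", "JENNIFER", "LINDA", "ELIZABETH", "BARBARA", "SUSAN",
    "JESSICA", "SARAH", "KAREN", "LISA", "NANCY", "BETTY", "MARGARET",
    "SANDRA", "ASHLEY", "KIMBERLY", "EMILY", "DONNA", "MICHELLE", "CAROL",
    "AMANDA", "DOROTHY", "MELISSA", "DEBORAH", "STEPHANIE", "REBECCA",
    "SHARON", "LAURA", "CYNTHIA", "KATHLEEN", "AMY", "ANGELA", "SHIRLEY",
    "ANNA", "RUTH", "BRENDA", "PAMELA", "NICOLE", "KATHERINE", "VIRGINIA",
    "CATHERINE", "CHRISTINE", "SAMANTHA", "DEBRA", "JANET", "RACHEL",
    "CAROLYN", "EMMA", "MAUREEN", "OLIVIA", "CHARLOTTE", "SOPHIE", "GRACE",
    "CHLOE", "LUCY", "HANNAH", "ALICE", "GEORGIA", "ISABELLA", "RUBY",
    "LACHLAN", "LIAM", "NOAH", "OLIVER", "ETHAN", "LUCAS", "COOPER",
    "ANGUS", "HAMISH", "CALLUM", "DUNCAN", "BRUCE", "NEIL", "IAN", "COLIN",
    "GRAHAM", "TREVOR", "WAYNE", "CRAIG", "GLENN", "RODNEY", "BARRY",
    "LEANNE", "NARELLE", "KYLIE", "TANYA", "FIONA", "BRONWYN", "JACQUELINE",
    "VANESSA", "NATALIE", "LOUISE", "CLAIRE", "MEGAN", "KATE", "JILLIAN",
    "ROSEMARY", "HEATHER", "JUDITH", "PAULINE", "VALERIE", "IRENE",
]

LAST_NAMES = [
    "SMITH", "JONES", "WILLIAMS", "BROWN", "WILSON", "TAYLOR", "JOHNSON",
    "WHITE", "MARTIN", "ANDERSON", "THOMPSON", "NGUYEN", "THOMAS", "WALKER",
    "HARRIS", "LEE", "RYAN", "ROBINSON", "KELLY", "KING", "DAVIS", "WRIGHT",
    "EVANS", "ROBERTS", "GREEN", "HALL", "WOOD", "JACKSON", "CLARKE",
    "PATEL", "KHAN", "LEWIS", "JAMES", "PHILLIPS", "MASON", "MITCHELL",
    "ROSE", "DAVIES", "RODGERS", "COOK", "CARTER", "RICHARDS", "BAILEY",
    "COLLINS", "BELL", "MURPHY", "COOPER", "HOWARD", "WARD", "TURNER",
    "PARKER", "CAMPBELL", "SCOTT", "HILL", "MOORE", "MORRIS", "ADAMS",
    "BAKER", "GRIFFITHS", "STEWART", "MURRAY", "GRANT", "HUGHES", "EDWARDS",
    "MARSHALL", "SIMPSON", "WEBB", "CHAPMAN", "GRAY", "HUNT", "ELLIS",
    "PRICE", "ROGERS", "BENNETT", "FISHER", "BARNES", "HENDERSON", "COLE",
    "PEARCE", "HARVEY", "GIBSON", "MILLS", "DEAN", "KNIGHT", "HARRISON",
    "BUTLER", "REID", "SHAW", "WALSH", "DIXON", "HUNTER", "FRASER",
    "KENNEDY", "STEVENS", "BYRNE", "PALMER", "GORDON", "REYNOLDS", "GRAHAM",
    "WALLACE", "POWELL", "MACDONALD", "FLEMING", "WATSON", "OCONNOR",
    "SULLIVAN", "FITZGERALD", "DOYLE", "MCCARTHY", "GALLAGHER", "DOHERTY",
    "KAUR", "SINGH", "CHEN", "WANG", "LIU", "ZHANG", "TRAN", "PHAM",
    "HOANG", "RUSSO", "COSTA", "FERRARI", "ROMANO", "RICCI", "MARINO",
    "GRECO", "BRUNO", "GALLO", "CONTI", "MANCINI", "LOMBARDI", "MORETTI",
    "BARBIERI", "FONTANA", "SANTORO", "MARIANI", "RINALDI", "CARUSO",
    "FERRARA", "GATTI", "PELLEGRINI", "PALUMBO", "SANNA", "FARINA", "RIZZI",
    "MONTI", "CATTANEO", "MORELLI", "AMATO", "SILVESTRI", "MAZZA", "VITALE",
]

SUBURBS = [
    "ARMADALE", "BALGA", "BASSENDEAN", "BAYSWATER", "BELMONT", "BENTLEY",
    "BICTON", "BOORAGOON", "BULLCREEK", "BURSWOOD", "CANNINGTON",
    "CLAREMONT", "COTTESLOE", "DIANELLA", "DUNCRAIG", "EMBLETON",
    "FLOREAT", "FREMANTLE", "GIRRAWHEEN", "GOSNELLS", "GREENWOOD",
    "HAMERSLEY", "HILTON", "INNALOO", "JOONDALUP", "KALAMUNDA",
    "KARDINYA", "KELMSCOTT", "KENSINGTON", "KEWDALE", "KINGSLEY",
    "LEEDERVILLE", "LYNWOOD", "MADDINGTON", "MANNING", "MAYLANDS",
    "MIDLAND", "MIRRABOOKA", "MORLEY", "MOSMANPARK", "MULLALOO",
    "MUNDARING", "MYAREE", "NEDLANDS", "NOLLAMARA", "NORANDA",
    "NORTHBRIDGE", "OSBORNE PARK", "PADBURY", "PALMYRA", "PARKWOOD",
    "PERTH", "QUEENSPARK", "REDCLIFFE", "RIVERVALE", "ROCKINGHAM",
    "ROLEYSTONE", "SCARBOROUGH", "SHENTONPARK", "SORRENTO", "SOUTHPERTH",
    "SPEARWOOD", "SUBIACO", "THORNLIE", "TUARTHILL", "VICTORIAPARK",
    "WANNEROO", "WARWICK", "WATERMANS BAY", "WEMBLEY", "WESTPERTH",
    "WILLAGEE", "WILLETTON", "WILSON", "WOODLANDS", "YANGEBUP", "YOKINE",
]

STREET_NAMES = [
    "ACACIA", "BANKSIA", "BOTTLEBRUSH", "CANNING", "CORAL", "DARLING",
    "EUCALYPT", "FORREST", "GERALDTON", "HAKEA", "HIBISCUS", "JACARANDA",
    "KANGAROO", "KOOKABURRA", "LAKESIDE", "MELALEUCA", "MULGA", "ORCHID",
    "PELICAN", "QUANDONG", "RIVERVIEW", "SHEOAK", "STIRLING", "SWAN",
    "TUART", "WARATAH", "WATTLE", "YARRA", "ALBANY", "BEAUFORT",
    "CAMBRIDGE", "HAMPTON", "KIMBERLEY", "LANCASTER", "NORFOLK", "OXFORD",
    "PRESTON", "RAILWAY", "STATION", "VICTORIA", "WELLINGTON", "YORK",
    "BOUNDARY", "CHURCH", "GEORGE", "HIGH", "KING", "MAIN", "QUEEN", "SHORT",
]

STREET_TYPES = ["STREET", "ROAD", "AVENUE", "WAY", "COURT", "DRIVE",
                "PLACE", "CRESCENT"]


def rank_weights(n: int, offset: float = 25.0) -> np.ndarray:
    """Shifted power-law rank weights, normalised to sum to 1."""
    w = 1.0 / (np.arange(1, n + 1) + offset)
    return w / w.sum()


def _table(values: list[str], offset: float = 25.0) -> dict[str, float]:
    return dict(zip(values, rank_weights(len(values), offset)))


def default_frequency_tables() -> dict[str, dict[str, float]]:
    """Default per-field value → probability tables.

    ``street_name``/``street_type`` are auxiliary tables used to build
    templated addresses ("number street-name street-type"); ``dob_year``
    spans 90 birth years with mild recency weighting; day and month are
    handled by the generator itself (uniform within valid calendar ranges).
    """
    years = [str(y) for y in range(1915, 2005)]
    year_w = np.linspace(0.8, 1.2, len(years))
    postcodes = [str(p) for p in range(6000, 6130)]
    return {
        "first_name": _table(FIRST_NAMES),
        "middle_name": _table(FIRST_NAMES[::-1]),
        "last_name": _table(LAST_NAMES),
        "sex": {"M": 0.5, "F": 0.5},
        "dob_year": dict(zip(years, year_w / year_w.sum())),
        "suburb": _table(SUBURBS, offset=15.0),
        "postcode": _table(postcodes, offset=40.0),
        "street_name": _table(STREET_NAMES, offset=15.0),
        "street_type": _table(STREET_TYPES, offset=4.0),
    }
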