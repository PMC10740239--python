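"""Synthetic name pools for the cohort simulator.

Roughly 100 given and 100 family names with a South African flavour
(Nguni, Sotho-Tswana, Afrikaans and English stock). The pools are small
on purpose: drawing ~10^4-10^5 patients from ~10^4 name combinations
produces cross-patient identity collisions at rates that exercise the
record-linkage stage. All names are synthetic pool entries, not records
of real people.
"""

GIVEN_NAMES = [
    "Thabo", "Sipho", "Bongani", "Mandla", "Themba", "Sibusiso", "Lwazi",
    "Andile", "Ayanda", "Kagiso", "Tshepo", "Lebogang", "Katlego", "Neo",
    "Tumelo", "Karabo", "Mpho", "Thato", "Refilwe", "Palesa", "Dineo",
    "Nthabiseng", "Boitumelo", "Kgomotso", "Lerato", "Ntombi", "Zanele",
    "Nomvula", "Thandiwe", "Nokuthula", "Busisiwe", "Nonhlanhla", "Zodwa",
    "Ntombizodwa", "Sindisiwe", "Phumzile", "Gugu", "Khanyisile", "Lindiwe",
    "Nompumelelo", "Xolani", "Vusi", "Sanele", "Mxolisi", "Siyabonga",
    "Nkosinathi", "Musa", "Sifiso", "Bheki", "Dumisani", "Jabulani",
    "Senzo", "Thulani", "Zweli", "Mzwandile", "Luyanda", "Anele", "Asanda",
    "Unathi", "Akhona", "Johannes", "Petrus", "Willem", "Jacobus", "Hendrik",
    "Pieter", "Frans", "Gert", "Daniel", "Stephanus", "Maria", "Anna",
    "Elizabeth", "Susanna", "Johanna", "Magdalena", "Catharina", "Sarah",
    "Esther", "Ruth", "David", "Samuel", "Joseph", "Moses", "Elias",
    "Isaac", "Solomon", "Abraham", "Emmanuel", "Gift", "Blessing",
    "Precious", "Patience", "Beauty", "Happy", "Justice", "Innocent",
    "Prudence", "Portia", "Pearl", "Grace", "Faith", "Charity",
]

FAMILY_NAMES = [
    "Nkosi", "Dlamini", "Ndlovu", "Khumalo", "Mokoena", "Molefe", "Mthembu",
    "Zulu", "Sithole", "Mahlangu", "Ngcobo", "Mkhize", "Cele", "Gumede",
    "Zungu", "Buthelezi", "Ntuli", "Shabalala", "Mazibuko", "Radebe",
    "Hadebe", "Kubheka", "Msimang", "Maseko", "Nxumalo", "Shongwe",
    "Mnguni", "Vilakazi", "Tshabalala", "Motaung", "Mofokeng", "Moloi",
    "Tsotetsi", "Nhlapo", "Kekana", "Masango", "Baloyi", "Chauke",
    "Maluleke", "Ngobeni", "Rikhotso", "Mathebula", "Shirinda", "Makhubela",
    "Sibiya", "Mavuso", "Magagula", "Masilela", "Skosana", "Mtsweni",
    "Mahlatsi", "Ramaphosa", "Sekhukhune", "Modise", "Pule", "Seabi",
    "Lekota", "Phala", "Mabena", "Ledwaba", "Botha", "Pretorius",
    "Van der Merwe", "Van Wyk", "Venter", "Joubert", "Du Plessis",
    "Fourie", "Le Roux", "Nel", "Coetzee", "Steyn", "Kruger", "Viljoen",
    "Swanepoel", "Marais", "Smit", "Meyer", "Erasmus", "Bezuidenhout",
    "Smith", "Williams", "Daniels", "Adams", "Jacobs", "Hendricks",
    "Petersen", "Arendse", "Abrahams", "Isaacs", "Fortuin", "September",
    "October", "April", "Booysen", "Cloete", "Davids", "Fredericks",
    "Jantjies", "Lottering", "Mostert", "Plaatjies",
]
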