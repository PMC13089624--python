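"""Deterministic ASCII name pool for the synthetic generator."""

FIRST_NAMES = [
    "Anna", "Minh", "Sok", "Aye", "Bounmy", "Linh", "Dara", "Htet", "Mai",
    "Phong", "Sreyneang", "Thiri", "Khamla", "Trang", "Vanna", "Nanda",
    "Somchai", "Huong", "Rithy", "Moe", "Keo", "Duc", "Chanthy", "Su",
    "Noy", "Quang", "Sophea", "Zaw", "Lien", "Vong", "Srey", "Kyaw",
    "Thao", "Bopha", "Win", "Lan", "Chan", "Nilar", "Hoa", "Piseth",
    "Aung", "Ngoc", "Samnang", "Khin", "Tuan", "Veasna", "Yadana", "Binh",
]

LAST_NAMES = [
    "Nguyen", "Sisavath", "Chea", "Aung", "Tran", "Phommachanh", "Sok",
    "Win", "Le", "Keomany", "Heng", "Myint", "Pham", "Vongsa", "Kim",
    "Htun", "Hoang", "Inthavong", "Chhun", "Thein", "Vu", "Sayavong",
    "Ly", "Lwin", "Dang", "Khamvongsa", "Ouk", "Soe", "Bui", "Phanthavong",
    "Meas", "Hlaing", "Do", "Chanthavong", "Pen", "Naing", "Ho",
    "Luangrath", "Sam", "Tin", "Truong", "Xaiyasin", "Kong", "Maung",
    "Dinh", "Syhalath", "Chan", "Oo",
]
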