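{
 "0.16": {
  "q0": [
   3.310390243762481,
   1.740670942812765,
   -1.9574895269072885,
   -0.40748164249949465,
   -0.23790942688073335,
   -0.23773925635178833,
   -0.19924680925546767,
   -0.8374592104081594
  ],
  "k_a": 0.7,
  "T_a": 0.012427225916609674,
  "mcot": 0.18715785351202993,
  "s": 0.5584683609090454,
  "max_floquet": 0.7089065277316435
 },
 "0.18": {
  "q0": [
   3.3402520252931427,
   1.7706118567638063,
   -1.9843524098623921,
   -0.4437963455178057,
   -0.27262006561116864,
   -0.27236594559883476,
   -0.21797431194511466,
   -1.0456873721301598
  ],
  "k_a": 0.65,
  "T_a": 0.01744113307055827,
  "mcot": 0.1916294993211476,
  "s": 0.6148874729994802,
  "max_floquet": 0.7734903211156441
 },
 "0.2": {
  "q0": [
   3.3697876288163116,
   1.8002382626996627,
   -2.0131209584051426,
   -0.4857774570078779,
   -0.306706640994162,
   -0.30634479604167775,
   -0.23149332788332538,
   -1.2722656981941987
  ],
  "k_a": 0.6,
  "T_a": 0.02381001534052469,
  "mcot": 0.20042585811838273,
  "s": 0.6728288127023268,
  "max_floquet": 0.7204164660485401
 },
 "0.22": {
  "q0": [
   3.3990011016141812,
   1.829557282247192,
   -2.0435597531098555,
   -0.5343665718584757,
   -0.3401404612923459,
   -0.33964460016256187,
   -0.23875440868245185,
   -1.51543605633932
  ],
  "k_a": 0.55,
  "T_a": 0.031641853045779725,
  "mcot": 0.214303085176537,
  "s": 0.732142580248695,
  "max_floquet": 0.521518544233994
 },
 "0.24": {
  "q0": [
   3.4276841640934737,
   1.858365303255734,
   -2.075637346397745,
   -0.5918517999654046,
   -0.3727262865744146,
   -0.37207964533140037,
   -0.23813792729781602,
   -1.772963014655146
  ],
  "k_a": 0.5,
  "T_a": 0.04138265767287794,
  "mcot": 0.23524507500718103,
  "s": 0.792803819782752,
  "max_floquet": 0.16925192628129682
 },
 "0.26": {
  "q0": [
   3.45533722066984,
   1.8861690714505341,
   -2.1093773549145984,
   -0.6623307448053288,
   -0.4040868427334052,
   -0.403246362648849,
   -0.22712267212220236,
   -2.0422909379475294
  ],
  "k_a": 0.45,
  "T_a": 0.05380849762756636,
  "mcot": 0.26711761475878354,
  "s": 0.8548051036984198,
  "max_floquet": 0.31447079359471936
 },
 "0.28": {
  "q0": [
   3.4799738786943,
   1.9107866276667653,
   -2.1331823044902083,
   -0.7012204417583322,
   -0.4343671226762561,
   -0.43279284420341374,
   -0.22076061006736908,
   -2.286376994841923
  ],
  "k_a": 0.45,
  "T_a": 0.061054113062415774,
  "mcot": 0.2716948532199764,
  "s": 0.9020758558659561,
  "max_floquet": 0.3735125523186792
 },
 "0.3": {
  "q0": [
   3.506629023883896,
   1.9376279826043645,
   -2.1673302445931224,
   -0.7864793824917834,
   -0.4639644241865084,
   -0.4625623343562054,
   -0.19098690548866773,
   -2.5784945289706234
  ],
  "k_a": 0.4,
  "T_a": 0.07522247085318107,
  "mcot": 0.31651326659198936,
  "s": 0.9644868196557735,
  "max_floquet": 0.42124984537981
 },
 "0.32": {
  "q0": [
   3.5291577730691497,
   1.9601304759365792,
   -2.189240555915191,
   -0.8269513688618005,
   -0.49036777412176935,
   -0.4899839426863155,
   -0.17385443593102143,
   -2.8235145661826353
  ],
  "k_a": 0.4,
  "T_a": 0.08347860272186398,
  "mcot": 0.32735187260878446,
  "s": 1.007772383691992,
  "max_floquet": 0.48101387885852254
 },
 "0.34": {
  "q0": [
   3.5478755145572314,
   1.980027806860488,
   -2.209884136048531,
   -0.8714214284969676,
   -0.42227844077737503,
   -0.5152091860463432,
   -0.15146563601381494,
   -3.058667276741444
  ],
  "k_a": 0.4,
  "T_a": 0.09398114107137892,
  "mcot": 0.3469853410730243,
  "s": 1.047806994720983,
  "max_floquet": 0.5574927085674809
 },
 "0.36": {
  "q0": [
   3.5529122473870447,
   1.9976109122390264,
   -2.2289707921876194,
   -0.9182261654012104,
   -0.009118484756245533,
   -0.5385983365689294,
   -0.1247560887182538,
   -3.285686292874551
  ],
  "k_a": 0.4,
  "T_a": 0.10619902474016239,
  "mcot": 0.37398444110071816,
  "s": 1.0845623623468132,
  "max_floquet": 0.64910549388456
 },
 "0.38": {
  "q0": [
   3.5791196242548877,
   2.0092205817373023,
   -2.2465934185487995,
   -0.9876859766574069,
   -4.352998165099284,
   -0.5567327381661481,
   -0.08433964633114806,
   -3.5002356742763907
  ],
  "k_a": 0.4,
  "T_a": 0.11960753301893247,
  "mcot": 0.4167024832912489,
  "s": 1.1174392460659939,
  "max_floquet": 0.7565720487860707
 },
 "0.4": {
  "q0": [
   3.6018283805408284,
   2.0422665701931617,
   -2.2770073619779576,
   -1.0494882238974006,
   -0.15976243530808917,
   -0.5921449644240779,
   -0.031326726798414035,
   -3.8724395922271593
  ],
  "k_a": 0.35,
  "T_a": 0.12625815275362287,
  "mcot": 0.4444357724213515,
  "s": 1.1784500739252677,
  "max_floquet": 0.6357710952613933
 },
 "0.42": {
  "q0": [
   3.6033132516869575,
   2.057453412786652,
   -2.2917195654322406,
   -1.0858435997922358,
   -0.4303706464176164,
   -0.6141705171920665,
   0.001120552466260223,
   -4.097130148060822
  ],
  "k_a": 0.35,
  "T_a": 0.13574540838576343,
  "mcot": 0.4675907615538021,
  "s": 1.2078272074508776,
  "max_floquet": 0.7096188169164336
 },
 "0.44": {
  "q0": [
   3.6371922671232944,
   2.0675077743147527,
   -2.304496968974163,
   -1.142528475023293,
   -5.097643577257656,
   -0.6319441889362594,
   0.047100439179180754,
   -4.32792409937324
  ],
  "k_a": 0.35,
  "T_a": 0.1451587407282274,
  "mcot": 0.5026726402361463,
  "s": 1.233865304173188,
  "max_floquet": 0.8184499218663854
 },
 "0.46": {
  "q0": [
   3.653666831063824,
   2.1061659654701046,
   -2.341416168625055,
   -1.2554010360176449,
   -0.020980168980463423,
   -0.6705737786345723,
   0.16537758813945488,
   -4.87655595722359
  ],
  "k_a": 0.3,
  "T_a": 0.16245618297836134,
  "mcot": 0.5762109515282445,
  "s": 1.3102102458728448,
  "max_floquet": 0.5872759556110625
 },
 "0.48": {
  "q0": [
   3.67164712852056,
   2.1231654082181177,
   -2.355985846121669,
   -1.2877064670685738,
   -3.0874232743386996,
   -0.6938247108327487,
   0.21062129729292225,
   -5.135089437259874
  ],
  "k_a": 0.3,
  "T_a": 0.17147615037471942,
  "mcot": 0.5974643631038518,
  "s": 1.33976611473858,
  "max_floquet": 0.6315132146551697
 }
}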