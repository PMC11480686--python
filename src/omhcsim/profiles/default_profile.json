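{
 "arrival_targets": {
  "counselor_online_mean": 102.49,
  "counselor_online_sd": 25.07,
  "seeker_online_mean": 113.26,
  "seeker_online_sd": 22.56
 },
 "chat_length_family": "lognormal",
 "chat_length_mean": 17.67,
 "chat_length_sd": 15.42,
 "counselor_birth_year_dist": {
  "1946": 0.0010918542490458048,
  "1947": 0.0011726966997788232,
  "1948": 0.0012595248412267254,
  "1949": 0.0013527818624938677,
  "1950": 0.0014529437670399686,
  "1951": 0.001560521802301933,
  "1952": 0.0016760650692083403,
  "1953": 0.0018001633249061335,
  "1954": 0.0019334499930051883,
  "1955": 0.002076605396705704,
  "1956": 0.002230360231310976,
  "1957": 0.0023954992938499684,
  "1958": 0.002572865488846497,
  "1959": 0.002763364130681273,
  "1960": 0.002967967564507008,
  "1961": 0.0031877201293026678,
  "1962": 0.0034237434883993717,
  "1963": 0.0036772423546860638,
  "1964": 0.00394951063971758,
  "1965": 0.004241938058111503,
  "1966": 0.004556017220943983,
  "1967": 0.004893351254350759,
  "1968": 0.005255661982220271,
  "1969": 0.005644798714745102,
  "1970": 0.006062747687690338,
  "1971": 0.006511642200558844,
  "1972": 0.006993773505400831,
  "1973": 0.007511602501846431,
  "1974": 0.00806777229805525,
  "1975": 0.008665121701696558,
  "1976": 0.009306699709820995,
  "1977": 0.009995781071583077,
  "1978": 0.010735883003249957,
  "1979": 0.011530783140813348,
  "1980": 0.012384538821838513,
  "1981": 0.013301507794968944,
  "1982": 0.014286370462792405,
  "1983": 0.015344153771600585,
  "1984": 0.01648025686998074,
  "1985": 0.01770047866720618,
  "1986": 0.0190110474320894,
  "1987": 0.02041865258337666,
  "1988": 0.021930478833948854,
  "1989": 0.023554242863107873,
  "1990": 0.025298232704131483,
  "1991": 0.02717135004813916,
  "1992": 0.02918315568019668,
  "1993": 0.03134391827957484,
  "1994": 0.033664666833249215,
  "1995": 0.036157246930170424,
  "1996": 0.03883438122364263,
  "1997": 0.0417097343704232,
  "1998": 0.04479798277800599,
  "1999": 0.04811488951609353,
  "2000": 0.051677384774621596,
  "2001": 0.055503652279011106,
  "2002": 0.05961322210372889,
  "2003": 0.0375,
  "2004": 0.0375,
  "2005": 0.0375,
  "2006": 0.0375
 },
 "counselor_gender_dist": {
  "female": 0.6,
  "male": 0.34,
  "nonbinary": 0.03,
  "transgender_female": 0.015,
  "transgender_male": 0.015
 },
 "counselor_idle_factor": 3.0,
 "counselor_topics_max": 3,
 "decision_rate": 1.25,
 "patience_family": "lognormal",
 "patience_mean": 4.16,
 "patience_sd": 3.27,
 "reference_year": 2021,
 "seeker_birth_year_dist": {
  "1951": 0.0009495000301950905,
  "1952": 0.0010320154278395726,
  "1953": 0.0011217017476872156,
  "1954": 0.001219182171916274,
  "1955": 0.0013251340397598857,
  "1956": 0.0014402935539734446,
  "1957": 0.0015654608963130597,
  "1958": 0.0017015057875697974,
  "1959": 0.0018493735307934201,
  "1960": 0.002010091579696742,
  "1961": 0.0021847766778809127,
  "1962": 0.002374642618488301,
  "1963": 0.002581008678200629,
  "1964": 0.002805308784185699,
  "1965": 0.0030491014776889104,
  "1966": 0.00331408074350124,
  "1967": 0.0036020877805518236,
  "1968": 0.003915123795412712,
  "1969": 0.004255363907610999,
  "1970": 0.0046251722633688765,
  "1971": 0.005027118462788899,
  "1972": 0.0054639954146281896,
  "1973": 0.005938838742724806,
  "1974": 0.0064549478789211545,
  "1975": 0.00701590898904787,
  "1976": 0.007625619891268522,
  "1977": 0.008288317139929386,
  "1978": 0.009008605463105463,
  "1979": 0.009791489758388392,
  "1980": 0.010642409869237982,
  "1981": 0.011567278383539457,
  "1982": 0.012572521717008409,
  "1983": 0.013665124766910033,
  "1984": 0.014852679446367355,
  "1985": 0.0161434374364974,
  "1986": 0.017546367522921633,
  "1987": 0.019071217915051297,
  "1988": 0.020728583981171063,
  "1989": 0.022529981869975704,
  "1990": 0.02448792853011646,
  "1991": 0.026616028683770016,
  "1992": 0.02892906935856281,
  "1993": 0.03144312263470242,
  "1994": 0.03417565732125067,
  "1995": 0.03714566033751719,
  "1996": 0.04037376864298753,
  "1997": 0.04388241263249636,
  "1998": 0.04769597199302182,
  "1999": 0.05184094510506653,
  "2000": 0.056346133165704554,
  "2001": 0.0612428403126667,
  "2002": 0.06656509114001939,
  "2003": 0.029733333333333334,
  "2004": 0.029733333333333334,
  "2005": 0.029733333333333334,
  "2006": 0.029733333333333334,
  "2007": 0.029733333333333334,
  "2008": 0.029733333333333334
 },
 "seeker_gender_dist": {
  "female": 0.64,
  "male": 0.31,
  "nonbinary": 0.03,
  "transgender_female": 0.01,
  "transgender_male": 0.01
 },
 "topic_dist": {
  "LGBTQ": 0.03499999999999999,
  "anxiety": 0.06499999999999997,
  "dating": 0.09499999999999996,
  "depression": 0.07499999999999997,
  "dissociative identity": 0.029999999999999985,
  "family": 0.04999999999999998,
  "health": 0.03499999999999999,
  "home": 0.03499999999999999,
  "intimacy": 0.03499999999999999,
  "lonely": 0.04999999999999998,
  "overwhelming": 0.03999999999999998,
  "pandemic": 0.04499999999999998,
  "parents": 0.08499999999999996,
  "romantic relationships": 0.05999999999999997,
  "self-improvement": 0.12499999999999994,
  "sexuality": 0.03999999999999998,
  "stress": 0.05499999999999997,
  "suicide": 0.04499999999999998
 }
}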