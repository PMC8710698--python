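{
 "sheet": {
  "parallel": [
   0.0067129674421309415,
   0.019064490708307565,
   -0.02509017552580777,
   0.013144546359853964,
   0.32420939979327845,
   -0.39745927205348247
  ],
  "antiparallel": [
   -0.10607070928246268,
   -2.1180467493700736,
   2.280303974886961,
   -0.04507889742931845,
   0.3619804611321728,
   -0.37856437659193204
  ],
  "spacing": 0.48
 },
 "barrel": {
  "12": [
   0.18596016320036027,
   0.9562829881577516,
   0.0,
   1.745427806621556,
   -0.8829803543937332,
   1.7633980639870446,
   1.352999323780458e-05,
   -0.1610538947950759,
   0.6569226175773045,
   1.4270972686494388,
   -0.2342558319226745,
   1.6552733030679672e-16,
   -0.003283828486554635,
   0.1977923426621675,
   -1.8322583417024754,
   0.4235412855835724,
   -1.6553211701757862,
   3.3099552309331054e-16
  ],
  "11": [
   0.1685061788065842,
   0.8753090537218687,
   0.0,
   1.7468899703775973,
   -0.8803179507180243,
   1.7655724668198705,
   1.2193180157657732e-05,
   -0.1520682289500168,
   0.5954719982568746,
   1.5802535620754672,
   -0.3472559995936713,
   1.6552733030679672e-16,
   0.004128736616001786,
   0.19202856602218846,
   -1.9787651436419391,
   0.5167729556782015,
   -1.8178793242326092,
   3.3099552309331054e-16
  ],
  "10": [
   0.15136718030282864,
   0.7940667091305574,
   0.0,
   1.7487110332667133,
   -0.8772145076095935,
   1.7684240374972902,
   -7.2852097308874784e-06,
   -0.15054137313575772,
   0.5138847599115747,
   1.7786942772242609,
   -0.4933270061261591,
   1.6552733030679672e-16,
   0.004302978939093569,
   0.1829702469786096,
   -2.1699455189288934,
   0.6401599880842723,
   -2.027263259921167,
   3.3099552309331054e-16
  ],
  "9": [
   0.13440119928105773,
   0.7125150224225955,
   0.0,
   1.7507106404750807,
   -0.8739291117533584,
   1.7718377789376054,
   -7.639535785891318e-06,
   -0.14718438556268548,
   0.402317178595314,
   2.0440822375085013,
   -0.6878683101501827,
   1.6552733030679672e-16,
   0.005442714027116623,
   0.16839147653386904,
   -2.4217850593005603,
   0.8090815010210745,
   -2.3028435347949814,
   3.3099552309331054e-16
  ],
  "8": [
   0.11768433965464362,
   0.6305232082180071,
   0.0,
   1.7528460560316153,
   -0.8704798321040347,
   1.7760350769323954,
   1.6493851930354444e-05,
   -0.14327324061296365,
   0.24374785976028326,
   2.412233035486276,
   -0.956111496084579,
   1.205138261596962e-16,
   0.005975503374717641,
   0.14385354246394588,
   -2.762669285671915,
   1.0505784231628355,
   -2.6753571126848485,
   2.589739164579497e-16
  ],
  "7": [
   0.10130201868193753,
   0.5478888083581506,
   0.0,
   1.7548417613882648,
   -0.8671358778718316,
   1.7811781450481061,
   1.3996380139311569e-05,
   -0.13732872123967924,
   0.00853987761364946,
   2.947299870570877,
   -1.3412101537947918,
   1.205138261596962e-16,
   0.006961523989900003,
   0.10083317194706971,
   -3.238772503277355,
   1.4153045125365846,
   -3.1942304243862547,
   2.589739164579497e-16
  ],
  "6": [
   0.085170662074064,
   0.4643019919551712,
   0.0,
   1.756436052627776,
   -0.8641343315436848,
   1.7877779364025266,
   -2.0929686802948784e-05,
   -0.12907294141554304,
   -0.35788257015356345,
   3.7722986198617687,
   -1.9211304676673056,
   6.592092089563653e-17,
   0.0062431050573505675,
   0.019335906434203545,
   -3.9311955136109415,
   2.005721623724593,
   -3.942102277745361,
   1.6870338144557725e-16
  ],
  "5": [
   0.06892281991242995,
   0.3792156398341648,
   0.0,
   1.7570525115403703,
   -0.8621185170800434,
   1.79656430441723,
   1.939730347198327e-05,
   -0.10795113145940792,
   -0.9605464529399922,
   5.146993885652592,
   -2.8523417987564925,
   6.592092089563653e-17,
   0.006573506020930227,
   -0.14607054190444888,
   -4.995765875484159,
   3.052709976293701,
   -5.0627772104274795,
   1.6870338144557725e-16
  ],
  "4": [
   0.0525376473202855,
   0.29184771181728525,
   0.0,
   1.7532233426535297,
   -0.8647343186777705,
   1.8036519463360965,
   -1.910326014677479e-05,
   -0.00016118979352363613,
   -2.091289312302352,
   7.755553572785529,
   -4.368709563226056,
   0.7799515478150526,
   0.015539527945990598,
   -0.5450367618670953,
   -6.749316526910311,
   4.992358454536914,
   -6.4677104981798275,
   0.20982896659153671
  ]
 }
}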