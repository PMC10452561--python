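variant	effect_allele	other_allele	eaf	beta	se	p	n
rs100000	A	T	0.6501831049456086	-1.310688677371266	0.0990953972374776	6.166583371985924e-40	1861
rs100007	C	T	0.3653055547412203	-2.2445476539282367	0.11770655168862987	4.568544405669092e-81	1861
rs100014	C	G	0.550536232794815	1.1129111971163108	0.06571816172889773	2.5002547214140535e-64	1861
rs100021	T	C	0.4758912790167454	-1.7581211565586403	0.06725880474922286	1.2925133498178357e-150	1861
rs100028	A	T	0.5031330136791168	-1.733891854993853	0.06510386298993096	2.8391383344727113e-156	1861
rs100035	C	T	0.16722138990107357	0.9753980575729748	0.08183956729660624	9.489488443224136e-33	1861
rs100042	C	G	0.3053405669973442	1.423379761066	0.09122647624594142	6.977443757321493e-55	1861
rs100049	T	C	0.6661701784651823	2.2677244553542923	0.09654339582587548	5.262674414169896e-122	1861
rs100056	A	G	0.5882080813273571	-1.0612306446857258	0.07752310414574742	1.1777046556828801e-42	1861
rs100063	C	T	0.8571298630958096	-2.3679943527000287	0.09887269986369848	9.255458821227229e-127	1861
rs100070	G	A	0.5626985641041987	0.9230369333738793	0.05150046850582089	7.816827401404268e-72	1861
rs100077	T	C	0.9171204788461405	-1.3186663515183024	0.11812050875526255	6.135670236408617e-29	1861
rs100084	A	G	0.5377316976067132	1.8999378754662415	0.07715626810710083	6.897474258570877e-134	1861
rs100091	C	T	0.10989857002491618	-2.5257951845862867	0.0514132172546106	0.0	1861
rs100098	G	A	0.6349002733090038	1.7811557842519758	0.08929058235023331	1.5645129686863664e-88	1861
rs100105	T	C	0.8465766655787685	2.019866061158082	0.05044101715326669	0.0	1861
rs100112	A	G	0.45223445829458464	-1.2585524355911029	0.07432806493207803	2.595822964510129e-64	1861
rs100119	C	T	0.2272871939763001	2.960410907578277	0.053702304629450234	0.0	1861
rs100126	G	A	0.4015860866631013	1.8212233030446343	0.06851395826079856	1.102540000551696e-155	1861
rs100133	T	C	0.5876642422580214	-1.215662796772118	0.09986647449496774	4.33502020149509e-34	1861
rs100140	A	G	0.5783630706160352	2.76404598349177	0.11417421725192561	1.7876837605354236e-129	1861
rs100147	C	T	0.7469186589751132	2.1004186335093857	0.05137695677280691	0.0	1861
rs100154	G	A	0.7429638874185596	1.8137361652566675	0.10910309905592488	4.66649117045126e-62	1861
rs100161	T	C	0.14090739985655298	2.110090510122963	0.09691848496901724	4.293695275871728e-105	1861
rs100168	A	G	0.5623422582360104	1.1171866905851098	0.07831104289561232	3.563572747717757e-46	1861
rs100175	C	T	0.5098354174473398	-2.3007710410057944	0.06846698275373067	1.461657438599276e-247	1861
rs100182	G	A	0.6113249670500122	-1.9332722124175106	0.10033036625170116	9.768748020590266e-83	1861
rs100189	T	C	0.9063857826686518	1.3888311273797513	0.0633358846279053	1.4037701350757116e-106	1861
rs100196	A	G	0.6994511261770067	-1.3724285138020411	0.0790080038934623	1.374110355873844e-67	1861
rs100203	C	T	0.7990519418379287	-0.8671541719361471	0.05241488667920266	1.767493845150526e-61	1861
rs100210	G	A	0.653233848977644	-0.8060010246024185	0.058970884088757294	1.5814839118675655e-42	1861
rs100217	T	C	0.6111432817186256	-2.570094746008115	0.11412696829869307	2.6670873835054964e-112	1861
rs100224	A	G	0.7254601977137064	1.2678679471516585	0.10167209272392354	1.0859860040303409e-35	1861
rs100231	C	T	0.42029649539217784	-1.3518987130101556	0.07935292764528848	4.4006290832689796e-65	1861
rs100238	G	A	0.453469537607243	2.0593143535361733	0.05198602024268084	0.0	1861
rs100245	T	C	0.2096774590481626	2.2985992252697036	0.11912991074232784	5.9284262614664046e-83	1861
rs100252	A	G	0.8496705118847746	1.609742137486751	0.11068313270966862	6.403698491276806e-48	1861
rs100259	C	T	0.9482446423122286	2.435772925486034	0.08291398013123727	1.0770127408603743e-189	1861
rs100266	G	A	0.5462603176721443	-1.8410039505406783	0.0642354106275714	1.1940828925082727e-180	1861
rs100273	T	C	0.24264769787344842	-2.5481256078046313	0.11080956557336807	5.1659628792957185e-117	1861
rs100280	A	G	0.07099957616856643	-2.649909033545675	0.05682160082471639	0.0	1861
rs100287	C	T	0.3104441885269382	2.2252282730932937	0.11304130289418392	2.894197141953049e-86	1861
rs100294	G	A	0.8498821770735289	-2.408117605056119	0.051960112315914464	0.0	1861
rs100301	T	C	0.6003630298219944	2.7881630691173234	0.10031977155965757	5.3064750902133426e-170	1861
rs100308	A	G	0.4132083785923916	-2.3903710674749243	0.06884454422266423	3.7609175653637405e-264	1861
rs100315	C	T	0.4772225535117986	2.6184757500902345	0.10439755945166411	7.86306598698082e-139	1861
rs100322	G	A	0.4146809094998096	2.1169380363162507	0.0721015253556633	1.7542027813026859e-189	1861
rs100329	T	C	0.5196381748839836	1.371664014179609	0.0605979588758368	1.9393210650911622e-113	1861
rs100336	A	G	0.4410819954767206	-2.2202899334042128	0.06389652516598492	1.4749699453879481e-264	1861
rs100343	C	T	0.22387341986145548	-2.551595710185449	0.11152998847808279	7.674964444504653e-116	1861
rs100350	G	A	0.8408652223252834	0.970902544391527	0.09853369958998587	6.619280751177717e-23	1861
rs100357	T	C	0.7626098466849217	2.758384069060237	0.05703259308720904	0.0	1861
rs100364	A	G	0.20873587766190876	2.6598015169609437	0.08132870756262174	1.355035510995277e-234	1861
rs100371	C	T	0.9157985608568279	1.6951485717947037	0.061754017683968966	6.945160923290601e-166	1861
rs100378	G	A	0.8758129720550601	-2.0022996811792075	0.08624833953705016	3.174284407533601e-119	1861
rs100385	T	C	0.579869393738896	1.477119753854631	0.07234473793497687	1.1620053042751284e-92	1861
rs100392	A	G	0.8619050845952507	-1.1159835721752713	0.09270878791409122	2.256465745372393e-33	1861
rs100399	C	T	0.5130805731316351	1.222808044788878	0.09725660270982073	2.971971890260106e-36	1861
rs100406	G	A	0.8074224930913965	1.999135776582316	0.05305419456952492	0.0	1861
rs100413	T	C	0.5412219489744173	1.2479522507543033	0.10842108058615452	1.1715702710216543e-30	1861
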