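probe_id	Bcell	CD4T	CD8T	Gran	Mono	NK
ref_Bcell_00	0.85750572799628	0.12383282805817453	0.11654114141471161	0.08351243139943551	0.08800997709467354	0.12241320672377572
ref_Bcell_01	0.8203159182739345	0.11927370510296598	0.11782416572512278	0.09807609717062325	0.08818194560915882	0.0867055367260464
ref_Bcell_02	0.8352921752592475	0.0967045783529588	0.1002728955374772	0.10320984112446956	0.12973001700606357	0.11755971515282519
ref_Bcell_03	0.8573307537664697	0.1293376088609131	0.08291852189413594	0.07961272203147068	0.10675237625638184	0.07263652047768301
ref_Bcell_04	0.8221408167264157	0.10089332921628222	0.09797236151951735	0.12503006639157113	0.10775357526946064	0.10084705879597083
ref_Bcell_05	0.8498124061236102	0.08485089532163986	0.07070764153255035	0.08154412863911864	0.11152192725291035	0.08203640343921972
ref_Bcell_06	0.8421721786361324	0.07022405452312457	0.11980286378810473	0.0792676648636864	0.08605595827382713	0.12281992923884973
ref_Bcell_07	0.8505874485921053	0.12082901478195215	0.10838303001655158	0.11450625684171142	0.07548973630378275	0.10246862928258933
ref_Bcell_08	0.850466334178021	0.12228036260157285	0.09167584354084946	0.1058910440324328	0.07355509854073022	0.09325790806664373
ref_Bcell_09	0.8393821807754924	0.07901198374422712	0.11898028622914456	0.09276677029301875	0.1287248730646733	0.10539950158063663
ref_CD4T_00	0.10630337522979108	0.8582797948472999	0.1105870146287673	0.07904728115010212	0.09641880803129126	0.08437383770977142
ref_CD4T_01	0.0941498978862389	0.8258022456359048	0.1280696830629293	0.08290024224135281	0.1103059097566771	0.08802520488874423
ref_CD4T_02	0.12244462156897026	0.8597328843003073	0.07789694894849836	0.12070445925247318	0.1266968902686988	0.12423500729175561
ref_CD4T_03	0.10418314887155664	0.8287275972256556	0.08154780969809995	0.12567434108467146	0.10313958926003583	0.0808331499069347
ref_CD4T_04	0.1230434136517882	0.8584943023133488	0.10418165646842847	0.09257727016779521	0.0946573169294278	0.0843693527609107
ref_CD4T_05	0.07228343720147434	0.8725731284865562	0.09806381300884577	0.10285811195282413	0.08932979858681352	0.11507949519129568
ref_CD4T_06	0.07151181224810563	0.8423311163539122	0.0718210176630467	0.07737352613230057	0.12802889412384205	0.10946564380231087
ref_CD4T_07	0.09569321478336888	0.8514244064746288	0.12236855251388647	0.09065264001976157	0.10541745893738289	0.11102106240037263
ref_CD4T_08	0.09132482662141073	0.8511459091897594	0.11591484299671137	0.124550758839433	0.07906373668460893	0.1260051635384457
ref_CD4T_09	0.07031073194892594	0.8651786502158653	0.11863160981903471	0.0782058430925549	0.09513421905479111	0.11891537667970274
ref_CD8T_00	0.07085627138107664	0.10770771687197744	0.867581419485882	0.10078021496933251	0.11355096523306524	0.08358540896182864
ref_CD8T_01	0.08191126887956038	0.0917876170330211	0.8307643616540288	0.09076368634674871	0.12688744368464888	0.10439996305666727
ref_CD8T_02	0.0904040840452504	0.08629147718852712	0.8771223694424513	0.0966686925788268	0.12882368505283537	0.10093136014637627
ref_CD8T_03	0.10126996774157344	0.12379243142296005	0.8645660450929024	0.10483917183116936	0.09559897023017551	0.12269127156509683
ref_CD8T_04	0.09469876899441332	0.12536557457010805	0.8241229211273117	0.09579981171406979	0.10117088919267155	0.12705629173491098
ref_CD8T_05	0.0850599547998855	0.11836234883572654	0.8605882719999156	0.11302515425686738	0.10777733097041223	0.12829364250769482
ref_CD8T_06	0.0899608875526795	0.09389653358076225	0.832174705132811	0.07304224331633624	0.08277449169852036	0.12492786382743451
ref_CD8T_07	0.12041012902950338	0.07674434448955475	0.8562267415190119	0.0987517896933775	0.10568109222929672	0.1095565003965438
ref_CD8T_08	0.08839956945333233	0.12768105068418742	0.8479504021036675	0.10768605129189442	0.1081135710339828	0.08103336379058147
ref_CD8T_09	0.07371192508938246	0.0946910094098785	0.865841805306308	0.11891330729750631	0.1137993549401239	0.0767922971515134
ref_Gran_00	0.12480129169186274	0.11812219467983703	0.122661481998972	0.8513982491785106	0.12493812610604395	0.07279913427723324
ref_Gran_01	0.07181733003589613	0.07121293440136882	0.08516612067714739	0.834914186392539	0.081250200061358	0.10402334910312375
ref_Gran_02	0.07233915046198272	0.10542327207009111	0.07996066918283302	0.8606724225140385	0.07126452126663348	0.0886342118231917
ref_Gran_03	0.12630047721187684	0.10230378279263469	0.11869524416480505	0.8594815648967036	0.10664504713681158	0.08147516080509384
ref_Gran_04	0.10446368489546837	0.07238118510754	0.1180998643055124	0.8776042550215706	0.12124054428051072	0.07304257875796367
ref_Gran_05	0.09031960500281311	0.08908019187173694	0.0767630195033722	0.8575967091596872	0.11784749052198001	0.08882328832013464
ref_Gran_06	0.12176855409512409	0.11782761477076778	0.0777482764884595	0.8660115494042893	0.1229572431941151	0.0818369541899048
ref_Gran_07	0.1044184707699114	0.10832499796132618	0.10656005544955599	0.8257747406576826	0.10967148766089696	0.10791728348077112
ref_Gran_08	0.11943312934012086	0.11821076194781971	0.08963009247595935	0.8633228399755932	0.12203640325434137	0.12357686549144738
ref_Gran_09	0.07969073961681997	0.07160214100517709	0.10904844660533372	0.8328805763646258	0.10382258345602416	0.12668827178841047
ref_Mono_00	0.09275917745515407	0.08516647302305841	0.09739060299771217	0.10943463479624402	0.8260659380712795	0.09283508581003257
ref_Mono_01	0.07802327133031137	0.10974677329685523	0.11983315193579104	0.09261122688452696	0.842303437166465	0.10237129953684608
ref_Mono_02	0.08290346677828561	0.08484457549700626	0.08979113699694485	0.09744554188829305	0.8248918876181544	0.11516392818202034
ref_Mono_03	0.10474327446575527	0.08798163237343008	0.07465279434106017	0.11579085708408887	0.8278647392974792	0.0779923985409807
ref_Mono_04	0.07784105474843661	0.07487573866695943	0.12438354192401543	0.08615465798040343	0.8383846347524115	0.11996765860012407
ref_Mono_05	0.1071954075827081	0.08122860319244313	0.09608880474259535	0.1230353478833288	0.8425224410211678	0.11265289319179203
ref_Mono_06	0.07580846253018808	0.11363948660431264	0.1165884114439148	0.11954600690212797	0.8604520594261127	0.09224396768957516
ref_Mono_07	0.07385272000996622	0.1011265740436177	0.11544759438293213	0.08145029220938063	0.8359742335967766	0.10216720254276233
ref_Mono_08	0.11489989377387516	0.12379520384555077	0.07754449105205016	0.0810562127719898	0.8679722182832885	0.10867129738140849
ref_Mono_09	0.11325836750859865	0.12980626990187882	0.12635079752145287	0.12058150401049517	0.8666269485431909	0.09370115291238622
ref_NK_00	0.10847374663658892	0.08106673854679475	0.11556966791684836	0.11546143987110333	0.11327771281808315	0.8466879414656067
ref_NK_01	0.09269081972744928	0.09518625594219648	0.0720003541066748	0.12065920698468958	0.10254219265328629	0.8432511183401039
ref_NK_02	0.10288172609596233	0.11329841311117975	0.09288765216390375	0.11983844040471953	0.12516780077832323	0.8432459378386387
ref_NK_03	0.07826896926099587	0.11562239775941094	0.12957693152491637	0.07887928892572388	0.1127605405636879	0.8695194040180024
ref_NK_04	0.12523431669978166	0.07740288485665446	0.07550859478909658	0.129272294910792	0.0770053891060953	0.8306084535482138
ref_NK_05	0.10449717602974115	0.09677638217737808	0.11502353147966998	0.08143343488948682	0.12486566569359517	0.8330316907784633
ref_NK_06	0.1161466594111984	0.07405621151644365	0.09840415526542992	0.07195349959871158	0.08882864238382618	0.8387338404505017
ref_NK_07	0.11318490634831455	0.09730104898914399	0.07340646174357501	0.1297216995657398	0.12332195840249996	0.8749794360984041
ref_NK_08	0.08479453180441833	0.09364661528349809	0.08363077005480121	0.07749438293065995	0.07198143547994415	0.8502001868791844
ref_NK_09	0.07738801936398339	0.08057826228208764	0.12162854082745725	0.09905456611803588	0.08102221126121496	0.8601918735890387
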